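"""Interval-censored data model, CSV I/O, and the packaged breast-cosmesis
fixture.

An observation is an inspection interval ``(L, R]`` known to contain the
latent event time; ``R = inf`` encodes right censoring and ``L = 0`` left
censoring (no separate flag is carried — the likelihood term S(L) - S(R)
covers both automatically).  On disk the CSV dialect is two columns
``left,right`` with right censoring written as ``Inf`` (an empty cell is also
accepted on read).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .exceptions import IntervalValidationError, ParseError

__all__ = [
    "IntervalObservation",
    "IntervalDataset",
    "read_intervals",
    "write_intervals",
    "cosmesis_fixture",
]

logger = logging.getLogger(__name__)

_INF_TOKENS = {"inf", "+inf", "infinity", "na", ""}


@dataclass(frozen=True)
class IntervalObservation:
    """A single inspection interval ``(left, right]`` with ``right = inf``
    for right-censored subjects."""

    left: float
    right: float

    def __post_init__(self) -> None:
        if not (self.left >= 0 and math.isfinite(self.left)):
            raise IntervalValidationError(
                f"left endpoint must be finite and >= 0, got {self.left}"
            )
        if not self.left < self.right:
            raise IntervalValidationError(
                f"require left < right, got ({self.left}, {self.right})"
            )

    @property
    def right_censored(self) -> bool:
        return math.isinf(self.right)


@dataclass(frozen=True)
class IntervalDataset:
    """An ordered, validated collection of interval observations."""

    observations: tuple[IntervalObservation, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.observations:
            raise IntervalValidationError("dataset must contain at least one observation")
        object.__setattr__(self, "observations", tuple(self.observations))

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[IntervalObservation]:
        return iter(self.observations)

    @property
    def n_right_censored(self) -> int:
        return sum(o.right_censored for o in self.observations)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (L, R) as float arrays with ``inf`` for right censoring."""
        left = np.array([o.left for o in self.observations], dtype=float)
        right = np.array([o.right for o in self.observations], dtype=float)
        return left, right

    @classmethod
    def from_arrays(cls, left: Iterable[float], right: Iterable[float],
                    label: str = "") -> "IntervalDataset":
        obs = tuple(IntervalObservation(float(l), float(r))
                    for l, r in zip(left, right, strict=True))
        return cls(obs, label=label)


def _parse_right(token: str, lineno: int) -> float:
    token = token.strip()
    if token.lower() in _INF_TOKENS:
        return math.inf
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: cannot parse right endpoint {token!r}") from None


def read_intervals(path: str | Path, label: str | None = None) -> IntervalDataset:
    """Read a two-column ``left,right`` CSV of inspection intervals.

    ``Inf`` (any case) or an empty right cell marks right censoring.  Raises
    :class:`ParseError` naming the line for malformed rows and
    :class:`IntervalValidationError` naming the row for inverted intervals.
    """
    path = Path(path)
    obs: list[IntervalObservation] = []
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    start = 1 if lines[0].lower().replace(" ", "").startswith("left") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected two comma-separated fields, got {line!r}")
        try:
            left = float(parts[0])
        except ValueError:
            raise ParseError(f"line {lineno}: cannot parse left endpoint {parts[0]!r}") from None
        right = _parse_right(parts[1], lineno)
        try:
            obs.append(IntervalObservation(left, right))
        except IntervalValidationError as err:
            raise IntervalValidationError(f"line {lineno}: {err}") from None
    ds = IntervalDataset(tuple(obs), label=label if label is not None else path.stem)
    logger.info("read %d intervals (%d right-censored) from %s",
                len(ds), ds.n_right_censored, path)
    return ds


def write_intervals(dataset: IntervalDataset, path: str | Path) -> None:
    """Write the dataset in the ``left,right`` CSV dialect (``Inf`` sentinel).

    Finite endpoints are written with :func:`repr` so a read round-trips
    bit-exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("left,right\n")
        for o in dataset:
            r = "Inf" if o.right_censored else repr(o.right)
            fh.write(f"{o.left!r},{r}\n")


def cosmesis_fixture() -> IntervalDataset:
    """The 48 radiotherapy-plus-chemotherapy intervals of the early breast
    cancer cosmesis study (time in months to moderate/severe breast
    retraction, patients inspected at irregular clinic visits).

    13 of the 48 subjects are right-censored.  The first interval is (8, 12].
    """
    with resources.as_file(
        resources.files("icweibull").joinpath("data/cosmesis_rct.csv")
    ) as p:
        return read_intervals(p, label="cosmesis radiotherapy+chemotherapy")
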