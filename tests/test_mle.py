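import math
import shutil
import subprocess
import time

import numpy as np
import pytest

import icweibull as icw
from icweibull.exceptions import NonIdentifiableError

from conftest import random_interval_dataset

# Interval-censored Weibull MLE for the cosmesis data computed with the
# independent oracle R survival::survreg(Surv(L, R, type="interval2") ~ 1,
# dist="weibull"); alpha = exp(intercept), beta = 1/scale.
SURVREG_ALPHA = 28.04247
SURVREG_BETA = 2.030238


def test_loglik_of_total_interval_is_zero():
    ds = icw.IntervalDataset.from_arrays([0.0], [math.inf])
    assert icw.log_likelihood(ds, icw.WeibullParams(3.0, 0.7)) == 0.0
    assert icw.score(ds, icw.WeibullParams(3.0, 0.7)) == (0.0, 0.0)


def test_loglik_matches_per_interval_summation_oracle(cosmesis):
    p = icw.WeibullParams(27.783, 2.11394)
    terms = []
    for o in cosmesis:
        sl = math.exp(-((o.left / p.scale) ** p.shape)) if o.left > 0 else 1.0
        sr = 0.0 if o.right_censored else math.exp(-((o.right / p.scale) ** p.shape))
        terms.append(math.log(sl - sr))
    assert icw.log_likelihood(cosmesis, p) == pytest.approx(math.fsum(terms), rel=1e-12)


def test_loglik_invariant_under_permutation(cosmesis, rng):
    p = icw.WeibullParams(20.0, 1.5)
    perm = rng.permutation(len(cosmesis))
    shuffled = icw.IntervalDataset(tuple(cosmesis.observations[i] for i in perm))
    assert icw.log_likelihood(shuffled, p) == pytest.approx(
        icw.log_likelihood(cosmesis, p), rel=1e-12)


def test_loglik_underflow_returns_minus_inf():
    ds = icw.IntervalDataset.from_arrays([500.0], [501.0])
    assert icw.log_likelihood(ds, icw.WeibullParams(1.0, 4.0)) == -math.inf


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_score_matches_finite_differences(seed, rng):
    ds = random_interval_dataset(40, np.random.default_rng(seed))
    for params in [icw.WeibullParams(2.0, 1.2), icw.WeibullParams(1.5, 0.9),
                   icw.WeibullParams(3.0, 1.8)]:
        ga, gb = icw.score(ds, params)
        a, b = params.scale, params.shape
        ha, hb = 1e-6 * a, 1e-6 * b
        fd_a = (icw.log_likelihood(ds, icw.WeibullParams(a + ha, b))
                - icw.log_likelihood(ds, icw.WeibullParams(a - ha, b))) / (2 * ha)
        fd_b = (icw.log_likelihood(ds, icw.WeibullParams(a, b + hb))
                - icw.log_likelihood(ds, icw.WeibullParams(a, b - hb))) / (2 * hb)
        assert ga == pytest.approx(fd_a, rel=1e-6, abs=1e-8)
        assert gb == pytest.approx(fd_b, rel=1e-6, abs=1e-8)


def test_mle_matches_survreg_oracle_frozen(cosmesis_mle):
    assert cosmesis_mle.converged
    assert cosmesis_mle.params.scale == pytest.approx(SURVREG_ALPHA, rel=1e-5)
    assert cosmesis_mle.params.shape == pytest.approx(SURVREG_BETA, rel=1e-5)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_mle_matches_survreg_oracle_live(tmp_path, cosmesis, cosmesis_mle):
    """Independent cross-check: R survival::survreg on the identical data."""
    csv = tmp_path / "cos.csv"
    icw.write_intervals(cosmesis, csv)
    script = tmp_path / "fit.R"
    script.write_text(
        'library(survival)\n'
        f'd <- read.csv("{csv}")\n'
        'R2 <- ifelse(is.infinite(d$right), NA, d$right)\n'
        'f <- survreg(Surv(d$left, R2, type="interval2") ~ 1, dist="weibull")\n'
        'cat(exp(coef(f)[1]), 1/f$scale, "\\n")\n'
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    alpha_r, beta_r = map(float, out.stdout.split())
    assert cosmesis_mle.params.scale == pytest.approx(alpha_r, rel=1e-4)
    assert cosmesis_mle.params.shape == pytest.approx(beta_r, rel=1e-4)


def test_score_vanishes_at_mle(cosmesis, cosmesis_mle):
    ga, gb = icw.score(cosmesis, cosmesis_mle.params)
    assert abs(ga) < 1e-6 and abs(gb) < 1e-6


def test_mle_is_local_maximum_against_random_points(cosmesis, cosmesis_mle, rng):
    best = cosmesis_mle.loglik
    for _ in range(100):
        p = icw.WeibullParams(float(rng.uniform(5, 80)), float(rng.uniform(0.3, 6)))
        assert icw.log_likelihood(cosmesis, p) <= best + 1e-9


def test_ci_is_estimate_plus_minus_1p96_se(cosmesis_mle):
    a, b = cosmesis_mle.params.scale, cosmesis_mle.params.shape
    assert cosmesis_mle.ci_scale == pytest.approx(
        (a - 1.96 * cosmesis_mle.se_scale, a + 1.96 * cosmesis_mle.se_scale))
    assert cosmesis_mle.ci_shape == pytest.approx(
        (b - 1.96 * cosmesis_mle.se_shape, b + 1.96 * cosmesis_mle.se_shape))


def test_full_information_se_close_to_diagonal(cosmesis):
    diag = icw.fit_mle(cosmesis)
    full = icw.fit_mle(cosmesis, full_information=True)
    assert full.params.scale == pytest.approx(diag.params.scale, rel=1e-8)
    # correlation between the parameters is modest here, so the two
    # conventions agree loosely but not exactly
    assert full.se_scale == pytest.approx(diag.se_scale, rel=0.1)
    assert full.se_scale != diag.se_scale


def test_scale_equivariance(cosmesis):
    kappa = 12.0
    left, right = cosmesis.to_arrays()
    scaled = icw.IntervalDataset.from_arrays(kappa * left, kappa * right)
    base = icw.fit_mle(cosmesis)
    fit = icw.fit_mle(scaled)
    assert fit.params.scale == pytest.approx(kappa * base.params.scale, rel=1e-6)
    assert fit.params.shape == pytest.approx(base.params.shape, rel=1e-6)


def test_all_right_censored_raises():
    ds = icw.IntervalDataset.from_arrays([1.0, 2.0, 3.0], [math.inf] * 3)
    with pytest.raises(NonIdentifiableError):
        icw.fit_mle(ds)


def test_single_repeated_interval_raises():
    ds = icw.IntervalDataset.from_arrays([1.0] * 5, [2.0] * 5)
    with pytest.raises(NonIdentifiableError):
        icw.fit_mle(ds)


def test_parameter_recovery_with_narrow_intervals():
    truth = icw.WeibullParams(2.0, 1.2)
    ds = icw.narrow_interval_dataset(2000, truth, rel_width=0.01, seed=42)
    fit = icw.fit_mle(ds)
    assert fit.params.scale == pytest.approx(truth.scale, rel=0.05)
    assert fit.params.shape == pytest.approx(truth.shape, rel=0.05)
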