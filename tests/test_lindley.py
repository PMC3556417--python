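import dataclasses
import math

import numpy as np
import pytest

import icweibull as icw
from icweibull import LossSpec, PriorSpec
from icweibull.exceptions import ApproximationError, CurvatureError
from icweibull.lindley import _point_estimate

from conftest import random_interval_dataset


def _fd_derivatives(ds, params):
    """Second derivatives from central differences of the log-likelihood and
    third derivatives from central differences of the analytic score."""
    a, b = params.scale, params.shape
    ha, hb = 1e-4 * a, 1e-4 * b
    ll = lambda aa, bb: icw.log_likelihood(ds, icw.WeibullParams(aa, bb))
    sc = lambda aa, bb: icw.score(ds, icw.WeibullParams(aa, bb))
    l20 = (ll(a + ha, b) - 2 * ll(a, b) + ll(a - ha, b)) / ha**2
    l02 = (ll(a, b + hb) - 2 * ll(a, b) + ll(a, b - hb)) / hb**2
    # d2(score)/dtheta2 at 5-point stencil for the third derivative
    l30 = (sc(a + ha, b)[0] - 2 * sc(a, b)[0] + sc(a - ha, b)[0]) / ha**2
    l03 = (sc(a, b + hb)[1] - 2 * sc(a, b)[1] + sc(a, b - hb)[1]) / hb**2
    return l20, l30, l02, l03


@pytest.mark.parametrize("seed", [3, 7])
def test_loglik_derivatives_match_finite_differences(seed):
    ds = random_interval_dataset(30, np.random.default_rng(seed))
    for params in (icw.WeibullParams(2.0, 1.2), icw.WeibullParams(2.4, 0.9)):
        t = icw.loglik_derivatives(ds, params)
        l20, l30, l02, l03 = _fd_derivatives(ds, params)
        assert t.l20 == pytest.approx(l20, rel=1e-5)
        assert t.l02 == pytest.approx(l02, rel=1e-5)
        assert t.l30 == pytest.approx(l30, rel=1e-4)
        assert t.l03 == pytest.approx(l03, rel=1e-4)


def test_negative_curvature_at_mle(cosmesis, cosmesis_mle, cosmesis_terms):
    assert cosmesis_terms.l20 < 0 and cosmesis_terms.l02 < 0
    assert cosmesis_terms.sigma11 == pytest.approx(-1 / cosmesis_terms.l20)
    assert cosmesis_terms.sigma22 == pytest.approx(-1 / cosmesis_terms.l02)


def test_derivatives_scale_equivariance():
    ds = random_interval_dataset(25, np.random.default_rng(9))
    params = icw.WeibullParams(2.0, 1.2)
    t1 = icw.loglik_derivatives(ds, params)
    kappa = 7.0
    left, right = ds.to_arrays()
    scaled = icw.IntervalDataset.from_arrays(kappa * left, kappa * right)
    t2 = icw.loglik_derivatives(scaled, icw.WeibullParams(kappa * 2.0, 1.2))
    assert t2.l20 == pytest.approx(t1.l20 / kappa**2, rel=1e-10)
    assert t2.l30 == pytest.approx(t1.l30 / kappa**3, rel=1e-10)
    assert t2.l02 == pytest.approx(t1.l02, rel=1e-10)
    assert t2.l03 == pytest.approx(t1.l03, rel=1e-10)


def test_curvature_error_when_not_concave():
    ds = random_interval_dataset(10, np.random.default_rng(4))
    # far into the tail the profile in the scale direction is convex
    with pytest.raises(CurvatureError):
        icw.loglik_derivatives(ds, icw.WeibullParams(500.0, 1.2))


def test_expectation_of_constant_is_constant(cosmesis, cosmesis_mle, cosmesis_terms):
    kappa = 4.25
    const = lambda a, b: kappa
    zero = lambda a, b: 0.0
    val = icw.lindley_expectation(cosmesis, PriorSpec(), const, zero, zero, zero,
                                  zero, at=cosmesis_mle.params, terms=cosmesis_terms)
    assert val == kappa


def test_expansion_collapses_to_mle_when_corrections_vanish(
        cosmesis, cosmesis_mle, cosmesis_terms):
    # Gamma(1, 0) priors have zero log-gradient; forcing l30 = 0 removes the
    # remaining correction for u = alpha, so the expansion returns the MLE.
    flat = PriorSpec(1.0, 0.0, 1.0, 0.0)
    no_skew = dataclasses.replace(cosmesis_terms, l30=0.0)
    one = lambda a, b: 1.0
    zero = lambda a, b: 0.0
    val = icw.lindley_expectation(cosmesis, flat, lambda a, b: a, one, zero,
                                  zero, zero, at=cosmesis_mle.params, terms=no_skew)
    assert val == cosmesis_mle.params.scale


def test_gelf_k_minus_one_equals_self_exactly(cosmesis, cosmesis_mle, cosmesis_terms):
    bs = icw.bayes_estimate(cosmesis, mle_result=cosmesis_mle, terms=cosmesis_terms)
    bg = icw.bayes_estimate(cosmesis, loss=LossSpec("gelf", -1.0),
                            mle_result=cosmesis_mle, terms=cosmesis_terms)
    assert bg.params.scale == bs.params.scale
    assert bg.params.shape == bs.params.shape


def test_linex_small_c_approaches_self(cosmesis, cosmesis_mle, cosmesis_terms):
    bs = icw.bayes_estimate(cosmesis, mle_result=cosmesis_mle, terms=cosmesis_terms)
    bl = icw.bayes_estimate(cosmesis, loss=LossSpec("linex", 1e-6),
                            mle_result=cosmesis_mle, terms=cosmesis_terms)
    assert bl.params.scale == pytest.approx(bs.params.scale, abs=1e-5)
    assert bl.params.shape == pytest.approx(bs.params.shape, abs=1e-5)


def test_linex_estimate_non_increasing_in_c(cosmesis, cosmesis_mle, cosmesis_terms):
    cs = [-1.4, -0.6, 0.6, 1.4]
    scales, shapes = [], []
    for c in cs:
        fit = icw.bayes_estimate(cosmesis, loss=LossSpec("linex", c),
                                 mle_result=cosmesis_mle, terms=cosmesis_terms)
        scales.append(fit.params.scale)
        shapes.append(fit.params.shape)
    assert all(x > y for x, y in zip(scales, scales[1:]))
    assert all(x > y for x, y in zip(shapes, shapes[1:]))


def test_linex_monotonicity_on_synthetic_data():
    ds = random_interval_dataset(60, np.random.default_rng(21))
    mle = icw.fit_mle(ds)
    terms = icw.loglik_derivatives(ds, mle.params)
    vals = [icw.bayes_estimate(ds, loss=LossSpec("linex", c),
                               mle_result=mle, terms=terms).params.scale
            for c in (-1.4, -0.6, 0.6, 1.4)]
    assert all(x > y for x, y in zip(vals, vals[1:]))


def test_loss_spec_validation():
    with pytest.raises(ValueError):
        LossSpec("linex", 0.0)
    with pytest.raises(ValueError):
        LossSpec("self", 0.5)
    with pytest.raises(ValueError):
        LossSpec("quadratic")
    with pytest.raises(ValueError):
        PriorSpec(-1.0, 0, 0, 0)


def test_back_transform_rejects_nonpositive_expectations():
    with pytest.raises(ApproximationError):
        _point_estimate(-0.1, LossSpec("linex", 0.6), "scale")
    with pytest.raises(ApproximationError):
        _point_estimate(0.0, LossSpec("gelf", 0.6), "shape")


def test_bayes_se_is_posterior_sd_near_curvature_sd(cosmesis, cosmesis_mle,
                                                    cosmesis_terms):
    bs = icw.bayes_estimate(cosmesis, mle_result=cosmesis_mle, terms=cosmesis_terms)
    assert bs.se_scale == pytest.approx(math.sqrt(cosmesis_terms.sigma11), rel=0.05)
    assert bs.se_shape == pytest.approx(math.sqrt(cosmesis_terms.sigma22), rel=0.05)
    assert bs.ci_shape[0] < bs.params.shape < bs.ci_shape[1]
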