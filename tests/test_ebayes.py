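"""E-Bayesian estimation: closed forms against brute-force hyperprior
quadrature (the module's central oracle), structural identities, E-MSE."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import beta as beta_dist

from chen_ghcs import (
    GammaPrior,
    HyperPrior,
    Loss,
    PosteriorGamma,
    SE,
    SufficientStats,
    bayes_lambda,
    bayes_reliability,
    ebayes_lambda,
    ebayes_reliability,
    emse_lambda,
)


def _brute_force_average(func, hyper: HyperPrior, tol=1e-10):
    """Nested quadrature of func(a, b) against the hyperprior density."""

    def inner(b):
        val, _ = integrate.quad(
            lambda a: func(a, b) * beta_dist.pdf(a, hyper.u, hyper.v), 0, 1, epsabs=tol
        )
        return val * float(hyper.b_density(b))

    val, _ = integrate.quad(inner, 0, hyper.c, epsabs=tol, limit=100)
    return val


def test_ebayes_lambda_hand_values(toy_stats):
    # m=2, Q=7, u=v=1, c=1: v1 = 2.5 ln(8/7)
    v1 = ebayes_lambda(toy_stats, HyperPrior(1, 1.0), SE)
    v2 = ebayes_lambda(toy_stats, HyperPrior(2, 1.0), SE)
    v3 = ebayes_lambda(toy_stats, HyperPrior(3, 1.0), SE)
    assert v1 == pytest.approx(2.5 * np.log(8 / 7), rel=1e-12)
    assert v2 == pytest.approx(2 * 2.5 * (8 * np.log(8 / 7) - 1), rel=1e-9)
    assert v3 == pytest.approx(2 * 2.5 * (1 - 7 * np.log(8 / 7)), rel=1e-9)
    assert 2 * v1 == pytest.approx(v2 + v3, abs=1e-12)


@pytest.mark.parametrize("variant", [1, 2, 3])
@pytest.mark.parametrize("loss", [SE, Loss("linex", 1.5), Loss("linex", -0.4)])
def test_ebayes_lambda_closed_form_equals_quadrature(variant, loss):
    rng = np.random.default_rng(17)
    for _ in range(8):
        stats = SufficientStats(int(rng.integers(1, 60)), float(rng.uniform(1.0, 40.0)))
        hyper = HyperPrior(variant, float(rng.uniform(0.2, 2.0)), float(rng.uniform(0.5, 3.0)), float(rng.uniform(0.5, 3.0)))
        closed = ebayes_lambda(stats, hyper, loss)
        brute = _brute_force_average(
            lambda a, b: bayes_lambda(PosteriorGamma(stats.m + a, stats.Q + b), loss), hyper
        )
        assert closed == pytest.approx(brute, abs=1e-8)


def test_variant_identity_and_limit(toy_stats):
    for loss in (SE, Loss("linex", 1.5)):
        v = [ebayes_lambda(toy_stats, HyperPrior(i, 1.3, 2.0, 1.5), loss) for i in (1, 2, 3)]
        assert 2 * v[0] == pytest.approx(v[1] + v[2], abs=1e-12)
    # c -> 0+: every variant converges to the Bayes estimate at (a_bar, b=0)
    target = bayes_lambda(
        PosteriorGamma(toy_stats.m + 0.5, toy_stats.Q), SE
    )
    for variant in (1, 2, 3):
        val = ebayes_lambda(toy_stats, HyperPrior(variant, 1e-6), SE)
        assert val == pytest.approx(target, rel=1e-6)


def test_ebayes_reliability_at_t_zero_is_one(toy_stats):
    for variant in (1, 2, 3):
        for loss in (SE, Loss("linex", 1.5)):
            assert ebayes_reliability(0.0, toy_stats, 1.0, HyperPrior(variant, 1.0), loss) == 1.0


@pytest.mark.parametrize("variant,loss", [(1, SE), (2, SE), (3, SE), (1, Loss("linex", 1.5))])
def test_ebayes_reliability_matches_brute_force(toy_stats, variant, loss):
    t, beta = 0.4, 1.0
    hyper = HyperPrior(variant, 1.0)
    val = ebayes_reliability(t, toy_stats, beta, hyper, loss)
    brute = _brute_force_average(
        lambda a, b: bayes_reliability(t, PosteriorGamma(toy_stats.m + a, toy_stats.Q + b), beta, loss),
        hyper,
        tol=1e-10,
    )
    assert val == pytest.approx(brute, abs=1e-7)


def test_ebayes_reliability_monte_carlo_cross_check(toy_stats):
    """Quadrature average equals a large Monte-Carlo average over (a, b)."""
    hyper = HyperPrior(1, 1.0)
    t, beta = 0.4, 1.0
    val = ebayes_reliability(t, toy_stats, beta, hyper, SE)
    rng = np.random.default_rng(8)
    a, b = hyper.sample_ab(200_000, rng)
    z = (toy_stats.Q + b) / (toy_stats.Q + b + np.expm1(t**beta))
    draws = z ** (toy_stats.m + a)
    mc_se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(val - draws.mean()) < 3 * mc_se


def test_ebayes_reliability_variant_ordering(toy_stats):
    """R-hat increases in b, so mass at larger b (variant 3) gives the largest
    estimate: EBS2 <= EBS1 <= EBS3."""
    vals = [ebayes_reliability(0.4, toy_stats, 1.0, HyperPrior(i, 1.0), SE) for i in (1, 2, 3)]
    assert vals[1] <= vals[0] <= vals[2]
    lam_vals = [ebayes_lambda(toy_stats, HyperPrior(i, 1.0), SE) for i in (1, 2, 3)]
    assert lam_vals[2] <= lam_vals[0] <= lam_vals[1]


def test_emse_hand_value_and_quadrature(toy_stats):
    # (2m+1)/(2 Q (Q+c)) with m=2, Q=7, c=1: 5/112
    assert emse_lambda(toy_stats, 1.0, SE) == pytest.approx(5 / 112, rel=1e-12)
    brute, _ = integrate.dblquad(
        lambda b, a: (toy_stats.m + a) / (toy_stats.Q + b) ** 2 / 1.0, 0, 1, 0, 1.0, epsabs=1e-12
    )
    assert emse_lambda(toy_stats, 1.0, SE) == pytest.approx(brute, abs=1e-10)


def test_emse_linex_quadrature_consistency(toy_stats):
    """LINEX E-MSE exceeds SE E-MSE (added squared bias) and matches an
    independent Monte-Carlo average of the posterior risk."""
    loss = Loss("linex", 1.5)
    val = emse_lambda(toy_stats, 1.0, loss)
    assert val > emse_lambda(toy_stats, 1.0, SE)
    rng = np.random.default_rng(4)
    a = rng.uniform(size=100_000)
    b = rng.uniform(size=100_000)
    post_var = (toy_stats.m + a) / (toy_stats.Q + b) ** 2
    mean = (toy_stats.m + a) / (toy_stats.Q + b)
    est = (toy_stats.m + a) / 1.5 * np.log1p(1.5 / (toy_stats.Q + b))
    risks = post_var + (est - mean) ** 2
    assert abs(val - risks.mean()) < 3 * risks.std(ddof=1) / np.sqrt(len(risks))


def test_emse_decreasing_in_Q():
    vals = [emse_lambda(SufficientStats(10, Q), 1.0, SE) for Q in (2.0, 5.0, 20.0)]
    assert vals[0] > vals[1] > vals[2]


def test_invalid_hyperprior():
    with pytest.raises(ValueError):
        HyperPrior(variant=4, c=1.0)
    with pytest.raises(ValueError):
        HyperPrior(variant=1, c=0.0)
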