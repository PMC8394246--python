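"""Two-parameter posterior: kernel reductions, Gibbs sampler recovery, and
Monte-Carlo E-Bayes averaging."""

import numpy as np
import pytest
from scipy import integrate

from chen_ghcs import (
    ChenParams,
    GammaPrior,
    GHCSDesign,
    HyperPrior,
    JointHyperPrior,
    JointPrior,
    Loss,
    MCMCConfig,
    SE,
    apply_ghcs,
    bayes_lambda,
    ebayes_joint,
    fit_joint,
    joint_log_posterior,
    posterior,
    sample,
    sufficient_stats,
)


@pytest.fixture(scope="module")
def toy_sample():
    x = np.sort(sample(30, ChenParams(2.0, 1.0), rng=1))
    return apply_ghcs(x, GHCSDesign(n=30, k=5, r=25, T=0.8))


@pytest.fixture(scope="module")
def flat_prior():
    return JointPrior(
        GammaPrior(1.0, 1e-9, allow_improper=True), GammaPrior(1.0, 1e-9, allow_improper=True)
    )


def test_fixed_beta_reduces_to_gamma_posterior(toy_sample):
    """At fixed beta the joint kernel renormalises to Gamma(m+a1, Q(beta)+b1)."""
    prior = JointPrior(GammaPrior(0.7, 0.3), GammaPrior(1.2, 0.5))
    beta = 1.1
    stats = sufficient_stats(toy_sample, beta)
    post = posterior(stats, prior.lambda_prior)
    norm, _ = integrate.quad(
        lambda lam: np.exp(joint_log_posterior(lam, beta, toy_sample, prior)
                           - joint_log_posterior(post.mean, beta, toy_sample, prior)),
        0, np.inf,
    )
    for lam in (0.5, 1.0, 2.5):
        lhs = np.exp(joint_log_posterior(lam, beta, toy_sample, prior)
                     - joint_log_posterior(post.mean, beta, toy_sample, prior)) / norm
        assert lhs == pytest.approx(post.pdf(lam), rel=1e-6)


def test_flat_prior_reduction_to_likelihood(toy_sample, flat_prior):
    """With a1=a2=1, b->0 the joint posterior is proportional to the censored
    likelihood, checked pointwise against an independent implementation."""

    def loglik(lam, beta):
        x = toy_sample.times
        m, n = toy_sample.m, toy_sample.n
        W = 1.0 - np.exp(x**beta)
        Wc = 1.0 - np.exp(toy_sample.t_star**beta)
        return (
            m * np.log(lam) + m * np.log(beta)
            + float(np.sum((beta - 1) * np.log(x) + x**beta + lam * W))
            + (n - m) * lam * Wc
        )

    ref = joint_log_posterior(1.0, 1.0, toy_sample, flat_prior) - loglik(1.0, 1.0)
    for lam, beta in [(0.5, 0.8), (2.0, 1.3), (3.0, 0.6)]:
        diff = joint_log_posterior(lam, beta, toy_sample, flat_prior) - loglik(lam, beta)
        assert diff == pytest.approx(ref, abs=1e-7)
    assert joint_log_posterior(-1.0, 1.0, toy_sample, flat_prior) == -np.inf


def test_joint_recovery_complete_sample(flat_prior):
    x = np.sort(sample(200, ChenParams(2.0, 1.0), rng=77))
    cs = apply_ghcs(x, GHCSDesign(n=200, k=2, r=200, T=float(x[-1] + 1)))
    fit = fit_joint(cs, flat_prior, MCMCConfig(n_iter=11_000, seed=5), SE, t=0.07)
    assert fit["lambda"].point == pytest.approx(2.0, rel=0.15)
    assert fit["beta"].point == pytest.approx(1.0, rel=0.15)
    assert fit["lambda"].cri_low < fit["lambda"].point < fit["lambda"].cri_high
    assert 0.0 < fit["reliability"].point < 1.0


def test_joint_linex_limits_to_se(toy_sample, flat_prior):
    cfg = MCMCConfig(n_iter=4000, seed=9)
    se_fit = fit_joint(toy_sample, flat_prior, cfg, SE)
    linex_fit = fit_joint(toy_sample, flat_prior, cfg, Loss("linex", 1e-8))
    assert linex_fit["lambda"].point == pytest.approx(se_fit["lambda"].point, rel=1e-6)
    assert linex_fit["beta"].point == pytest.approx(se_fit["beta"].point, rel=1e-6)


def test_constant_beta_chain_matches_single_parameter_closed_form(toy_sample):
    """Holding beta at truth (point-mass prior), the lam marginal reproduces
    the single-parameter closed form."""
    prior = JointPrior(GammaPrior(0.6119, 0.1523), GammaPrior(1e6, 1e6))  # beta pinned near 1
    fit = fit_joint(toy_sample, prior, MCMCConfig(n_iter=20_000, seed=11), SE, return_chains=True)
    stats = sufficient_stats(toy_sample, 1.0)
    closed = bayes_lambda(posterior(stats, GammaPrior(0.6119, 0.1523)), SE)
    draws = fit["chains"]["lambda"][2000:]
    mc_se = draws.std(ddof=1) / np.sqrt(len(draws) / 5)
    assert abs(fit["lambda"].point - closed) < 3 * mc_se + 0.02 * closed


def test_ebayes_joint_point_mass_limit_and_finiteness(toy_sample):
    hyper = JointHyperPrior(HyperPrior(1, 1e-6, 1e6, 1e6), HyperPrior(1, 1e-6, 1e6, 1e6))
    cfg = MCMCConfig(n_iter=3000, seed=21)
    eb = ebayes_joint(toy_sample, hyper, cfg, SE, n_draws=4)
    prior = JointPrior(
        GammaPrior(0.5, 5e-7, allow_improper=True), GammaPrior(0.5, 5e-7, allow_improper=True)
    )
    direct = fit_joint(toy_sample, prior, MCMCConfig(n_iter=3000, seed=22), SE)
    assert eb["lambda"] == pytest.approx(direct["lambda"].point, rel=0.1)
    assert eb["lambda"] > 0 and eb["beta"] > 0
    assert np.isfinite(eb["lambda_mc_se"])
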