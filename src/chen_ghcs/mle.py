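"""Maximum-likelihood estimation from a GHCS-censored Chen sample.

With beta fixed, the likelihood is ``L(lam) ∝ lam^m e^{-lam Q(beta)}`` so
``lam_hat = m / Q``.  For unknown beta the profile log-likelihood

    l_p(beta) = m ln(m / Q(beta)) + m ln beta
                + sum[(beta - 1) ln x_i + x_i^beta] - m

is maximised by a log-grid scan to bracket a sign change of the analytic
profile score, followed by Brent root refinement.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .censoring import CensoredSample, SufficientStats, sufficient_stats

__all__ = ["mle_lambda", "mle_beta", "profile_loglik", "profile_score"]


def mle_lambda(stats: SufficientStats) -> float:
    """Closed-form MLE of the scale parameter: m / Q."""
    return stats.m / stats.Q


def _q_and_deriv(sample: CensoredSample, beta: float) -> tuple[float, float]:
    """Q(beta) and dQ/dbeta, including the censored-tail term."""
    x = sample.times
    c = sample.t_star
    n_m = sample.n - sample.m
    with np.errstate(over="ignore", invalid="ignore"):
        xb = x**beta
        Q = float(np.sum(np.expm1(xb)) + n_m * np.expm1(c**beta))
        dQ = float(np.sum(np.exp(xb) * xb * np.log(x)) + n_m * np.exp(c**beta) * c**beta * np.log(c))
    return Q, dQ


def profile_loglik(beta: float, sample: CensoredSample) -> float:
    """Profile log-likelihood l_p(beta) with lam profiled out at m/Q(beta)."""
    if beta <= 0:
        return -np.inf
    x = sample.times
    m = sample.m
    Q, _ = _q_and_deriv(sample, beta)
    return m * np.log(m / Q) + m * np.log(beta) + float(np.sum((beta - 1.0) * np.log(x) + x**beta)) - m


def profile_score(beta: float, sample: CensoredSample) -> float:
    """d l_p / d beta, analytic."""
    x = sample.times
    m = sample.m
    Q, dQ = _q_and_deriv(sample, beta)
    xb = x**beta
    return -m * dQ / Q + m / beta + float(np.sum(np.log(x) * (1.0 + xb)))


def mle_beta(sample: CensoredSample, bracket: tuple[float, float] = (1e-2, 20.0)) -> float:
    """Profile MLE of the shape parameter.

    Scans a log-spaced grid over ``bracket`` for a sign change of the profile
    score, then refines with Brent's method to 1e-10 relative tolerance.
    Raises ``RuntimeError`` (with the scanned score values) if no sign change
    is found.
    """
    if sample.m < 2:
        raise ValueError("need at least 2 observed failures to estimate beta")
    lo, hi = bracket
    grid = np.geomspace(lo, hi, 200)
    scores = np.array([profile_score(b, sample) for b in grid])
    finite = np.isfinite(scores)
    grid, scores = grid[finite], scores[finite]
    sign_change = np.nonzero(np.diff(np.sign(scores)) != 0)[0]
    if len(sign_change) == 0:
        raise RuntimeError(
            "profile score has no sign change in bracket "
            f"[{lo}, {hi}]; endpoint scores: {scores[0]:.4g}, {scores[-1]:.4g}"
        )
    i = sign_change[0]
    root = brentq(profile_score, grid[i], grid[i + 1], args=(sample,), rtol=1e-12, xtol=1e-14)
    return float(root)


def fit_mle(sample: CensoredSample, beta: float | None = None) -> tuple[float, float]:
    """Convenience wrapper: (lam_hat, beta_hat); beta fixed if supplied."""
    b = mle_beta(sample) if beta is None else beta
    return mle_lambda(sufficient_stats(sample, b)), b
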