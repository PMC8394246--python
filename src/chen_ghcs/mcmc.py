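"""Metropolis-Hastings sampling from the single-parameter posterior.

The posterior of lam is an exact Gamma(m + a, Q + b), so the sampler here is
primarily a cross-check of the closed forms and the template for the
two-parameter Gibbs sampler.  The chain is a random walk: proposals are
Normal(current, proposal_sd) with negative proposals auto-rejected through a
-inf log kernel; the default proposal scale is the MLE's asymptotic standard
deviation sqrt(m)/Q.  One proposal normal and one comparison uniform are
consumed per iteration, in fixed order, so a fixed seed gives a
bit-reproducible chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .bayes import EstimateReport, GammaPrior, Loss, SE
from .censoring import SufficientStats, p_star as _p_star

__all__ = ["MCMCConfig", "log_kernel", "run_chain", "chain_estimates"]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings: total iterations N, burn-in (default N/10), proposal
    scale (default sqrt(m)/Q), seed, and credible level gamma."""

    n_iter: int = 11000
    burn_in: Optional[int] = None
    proposal_sd: Optional[float] = None
    seed: Optional[int] = None
    gamma_level: float = 0.05

    def __post_init__(self) -> None:
        if self.n_iter < 2:
            raise ValueError("n_iter must be >= 2")
        if self.burn_in is not None and not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.proposal_sd is not None and not self.proposal_sd > 0:
            raise ValueError("proposal_sd must be positive")

    def resolved_burn_in(self) -> int:
        return self.n_iter // 10 if self.burn_in is None else self.burn_in


def log_kernel(lam, stats: SufficientStats, prior: GammaPrior):
    """Unnormalised log posterior: (m + a - 1) ln lam - (Q + b) lam; -inf off-domain."""
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            lam > 0,
            (stats.m + prior.a - 1.0) * np.log(np.where(lam > 0, lam, 1.0)) - (stats.Q + prior.b) * lam,
            -np.inf,
        )
    return out[()] if np.ndim(out) == 0 else out


def run_chain(
    stats: SufficientStats, prior: GammaPrior, config: MCMCConfig
) -> tuple[np.ndarray, float]:
    """Random-walk Metropolis chain for lam; returns (chain, acceptance rate).

    The chain starts at the MLE m/Q.  Acceptance uses log-kernel differences
    only, never normalising constants.
    """
    rng = np.random.default_rng(config.seed)
    sd = config.proposal_sd if config.proposal_sd is not None else np.sqrt(stats.m) / stats.Q
    n = config.n_iter
    steps = rng.normal(0.0, sd, size=n)
    unifs = rng.uniform(size=n)

    chain = np.empty(n)
    cur = stats.m / stats.Q
    cur_lk = log_kernel(cur, stats, prior)
    accepted = 0
    for v in range(n):
        prop = cur + steps[v]
        prop_lk = log_kernel(prop, stats, prior)
        if np.log(unifs[v]) < prop_lk - cur_lk:
            cur, cur_lk = prop, prop_lk
            accepted += 1
        chain[v] = cur
    return chain, accepted / n


def _point_estimate(draws: np.ndarray, loss: Loss) -> float:
    if loss.kind == "se":
        return float(np.mean(draws))
    h = loss.h
    # -(1/h) ln mean(e^{-h x}), overflow-guarded
    return float(-(logsumexp(-h * draws) - np.log(len(draws))) / h)


def chain_estimates(
    chain: np.ndarray,
    loss: Loss = SE,
    beta: Optional[float] = None,
    t: Optional[float] = None,
    burn_in: Optional[int] = None,
    gamma_level: float = 0.05,
) -> dict[str, EstimateReport]:
    """Point estimates and chain-quantile credible intervals from a lam chain.

    Returns a dict with key 'lambda' and, when (beta, t) are given, key
    'reliability' computed from the per-draw transform R = exp{lam(1 - e^{t^beta})}.
    """
    chain = np.asarray(chain, dtype=float)
    delta = len(chain) // 10 if burn_in is None else burn_in
    if delta >= len(chain):
        raise ValueError("burn-in must leave a nonempty chain")
    draws = chain[delta:]

    def report(vals: np.ndarray, label: str) -> EstimateReport:
        lo, hi = np.quantile(vals, [gamma_level / 2, 1 - gamma_level / 2])
        return EstimateReport(
            point=_point_estimate(vals, loss), loss=loss, cri_low=float(lo), cri_high=float(hi), method=label
        )

    out = {"lambda": report(draws, "mcmc-lambda")}
    if t is not None:
        if beta is None:
            raise ValueError("beta is required to transform the chain to R(t)")
        r_draws = np.exp(-draws * _p_star(t, beta))
        out["reliability"] = report(r_draws, "mcmc-reliability")
    return out
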