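"""The Chen bathtub-shaped lifetime distribution.

A two-parameter lifetime law with cdf ``F(x) = 1 - exp{lam * (1 - e^{x^beta})}``.
Its hazard ``h(x) = lam * beta * e^{x^beta} * x^{beta-1}`` is bathtub-shaped for
``beta < 1`` and increasing otherwise; ``beta = 1`` gives the exponential power
special case.  The key structural fact, used throughout the inference modules,
is that ``Y = e^{X^beta} - 1`` is Exponential(lam).

All densities are computed on the log scale internally so that ``e^{x^beta}``
never overflows before the surrounding exponential tames it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChenParams", "pdf", "logpdf", "cdf", "reliability", "hazard", "sample"]


@dataclass(frozen=True)
class ChenParams:
    """Parameter pair (lambda_, beta) of the Chen distribution.

    lambda_ is the scale-type parameter (it barely affects the hazard's shape);
    beta is the shape parameter that decides bathtub (< 1) versus increasing
    (>= 1) hazard.  Both must be strictly positive.
    """

    lambda_: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.lambda_ > 0 and np.isfinite(self.lambda_)):
            raise ValueError(f"lambda_ must be a positive finite real, got {self.lambda_}")
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValueError(f"beta must be a positive finite real, got {self.beta}")


def _validate_nonneg(x, name: str = "x"):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be nonnegative")
    return x


def logpdf(x, params: ChenParams):
    """Log-density ln f(x) = ln(lam*beta) + (beta-1) ln x + x^beta + lam(1 - e^{x^beta})."""
    x = _validate_nonneg(x)
    lam, beta = params.lambda_, params.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        xb = x**beta
        out = np.log(lam * beta) + (beta - 1.0) * np.log(x) + xb - lam * np.expm1(xb)
    # x = 0 limits: +inf for beta < 1, ln(lam) for beta = 1, -inf for beta > 1
    if beta == 1.0:
        out = np.where(x == 0.0, np.log(lam), out)
    elif beta < 1.0:
        out = np.where(x == 0.0, np.inf, out)
    else:
        out = np.where(x == 0.0, -np.inf, out)
    return out[()] if np.ndim(out) == 0 else out


def pdf(x, params: ChenParams):
    """Density f(x; lam, beta) = lam*beta*x^{beta-1} * exp{lam(1 - e^{x^beta}) + x^beta}."""
    return np.exp(logpdf(x, params))


def cdf(x, params: ChenParams):
    """Distribution function F(x) = 1 - exp{lam * (1 - e^{x^beta})}."""
    x = _validate_nonneg(x)
    out = -np.expm1(-params.lambda_ * np.expm1(x**params.beta))
    return out[()] if np.ndim(out) == 0 else out


def reliability(t, params: ChenParams):
    """Survival function R(t) = exp{lam * (1 - e^{t^beta})}; R(0) = 1."""
    t = _validate_nonneg(t, "t")
    out = np.exp(-params.lambda_ * np.expm1(t**params.beta))
    return out[()] if np.ndim(out) == 0 else out


def hazard(x, params: ChenParams):
    """Hazard rate h(x) = lam * beta * e^{x^beta} * x^{beta-1}.

    At ``x = 0`` this diverges to +inf when ``beta < 1`` (the bathtub's left
    wall), equals lam when ``beta = 1``, and is 0 when ``beta > 1``.
    """
    x = _validate_nonneg(x)
    lam, beta = params.lambda_, params.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        out = lam * beta * np.exp(x**beta) * x ** (beta - 1.0)
    if beta < 1.0:
        out = np.where(x == 0.0, np.inf, out)
    elif beta == 1.0:
        out = np.where(x == 0.0, lam, out)
    return out[()] if np.ndim(out) == 0 else out


def inverse_cdf(u, params: ChenParams):
    """Quantile transform X = [ln(1 - ln(1-u)/lam)]^{1/beta} for u in [0, 1)."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u must lie in [0, 1)")
    out = np.log1p(-np.log1p(-u) / params.lambda_) ** (1.0 / params.beta)
    return out[()] if np.ndim(out) == 0 else out


def sample(n: int, params: ChenParams, rng=None):
    """Draw ``n`` i.i.d. lifetimes by the inverse-CDF transform of Uniform(0,1).

    Exactly one uniform is consumed per variate, in index order, so a fixed
    seed yields a bit-reproducible vector.  ``rng`` may be a seed or a
    ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    return inverse_cdf(rng.uniform(size=n), params)
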