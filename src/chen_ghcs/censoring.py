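"""Generalized Type-I hybrid censoring (Type-I GHCS).

The rule guarantees at least ``k`` failures while capping the test duration
near ``T``: the experiment stops at ``T* = max(X_{k:n}, min(X_{r:n}, T))``.
Writing ``D`` for the number of failures at or before ``T``, three cases
arise:

* case I   (``D < k``):      stop at ``X_{k:n}``; ``m = k`` failures observed;
* case II  (``k <= D < r``): stop at ``T``;       ``m = D``;
* case III (``D >= r``):     stop at ``X_{r:n}``; ``m = r``.

Because ``Y = e^{X^beta} - 1`` is Exponential(lam) under the Chen law, the
censored data reduce to the exponential-family sufficient statistic

    Q = sum_{i<=m} (e^{x_i^beta} - 1) + (n - m) * (e^{T*^beta} - 1),

the "total transformed time on test": every estimator downstream consumes
only ``(m, Q)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["GHCSDesign", "CensoredSample", "SufficientStats", "apply_ghcs", "sufficient_stats", "p_star"]


@dataclass(frozen=True)
class GHCSDesign:
    """Stopping-rule parameters: sample size n, minimum failures k, ideal
    failures r, and time cap T (same units as the lifetimes).  Requires
    0 < k < r <= n and T > 0."""

    n: int
    k: int
    r: int
    T: float

    def __post_init__(self) -> None:
        if not (0 < self.k < self.r <= self.n):
            raise ValueError(f"need 0 < k < r <= n, got n={self.n}, k={self.k}, r={self.r}")
        if not self.T > 0:
            raise ValueError(f"T must be positive, got {self.T}")


@dataclass(frozen=True)
class CensoredSample:
    """Outcome of applying a GHCS design to an ordered sample."""

    design: GHCSDesign
    times: np.ndarray  # the m observed order statistics x_{1:n} .. x_{m:n}
    case: str  # "I", "II" or "III"
    m: int
    D: int  # failures at or before T
    t_star: float  # termination time

    @property
    def n(self) -> int:
        return self.design.n


@dataclass(frozen=True)
class SufficientStats:
    """(m, Q) reduction of a censored Chen sample at a given beta, plus the
    transformed reliability time point P* = e^{t^beta} - 1 when requested."""

    m: int
    Q: float
    p_star: Optional[float] = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("no observed failures: inference undefined for m = 0")
        if not self.Q > 0:
            raise ValueError(f"Q must be positive, got {self.Q}")


def apply_ghcs(sorted_times, design: GHCSDesign) -> CensoredSample:
    """Apply the three-case stopping rule to a full ordered sample of size n.

    The input must be the complete sorted sample; the returned object keeps
    only the ``m`` observed failures.  ``t_star`` always equals
    ``max(x_k, min(x_r, T))``.
    """
    x = np.asarray(sorted_times, dtype=float)
    if x.ndim != 1 or len(x) != design.n:
        raise ValueError(f"expected exactly n={design.n} lifetimes, got {len(x)}")
    if np.any(np.diff(x) < 0):
        raise ValueError("lifetimes must be sorted ascending")
    if np.any(x <= 0):
        raise ValueError("lifetimes must be strictly positive")

    # D counts failures with x <= T (closed boundary: x = T is a pre-T failure)
    D = int(np.searchsorted(x, design.T, side="right"))
    if D < design.k:
        case, m, t_star = "I", design.k, x[design.k - 1]
    elif D < design.r:
        case, m, t_star = "II", D, design.T
    else:
        case, m, t_star = "III", design.r, x[design.r - 1]
    return CensoredSample(design=design, times=x[:m].copy(), case=case, m=m, D=D, t_star=float(t_star))


def p_star(t: float, beta: float) -> float:
    """Transformed reliability time point P* = e^{t^beta} - 1."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return float(np.expm1(t**beta))


def sufficient_stats(sample: CensoredSample, beta: float, t: Optional[float] = None) -> SufficientStats:
    """Reduce a censored sample to (m, Q) at shape parameter ``beta``.

    Q sums the exponential transform ``e^{x^beta} - 1`` over the observed
    failures and adds the censored-tail contribution ``(n - m)`` times the
    transform of the termination time (x_k, T, or x_r by case — always
    ``t_star``).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    obs = float(np.sum(np.expm1(sample.times**beta)))
    tail = (sample.n - sample.m) * float(np.expm1(sample.t_star**beta))
    return SufficientStats(m=sample.m, Q=obs + tail, p_star=None if t is None else p_star(t, beta))
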