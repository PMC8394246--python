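"""Simulate a life test, censor it, and recover the parameters by ML.

Draws n = 120 lifetimes from a Chen(2, 1) law, applies the generalized
Type-I hybrid censoring rule (stop at max(x_k, min(x_r, T))), and estimates
lam in closed form and beta by profile likelihood.
"""

import numpy as np

from chen_ghcs import (
    ChenParams,
    GHCSDesign,
    apply_ghcs,
    mle_beta,
    mle_lambda,
    sample,
    sufficient_stats,
)

params = ChenParams(lambda_=2.0, beta=1.0)
design = GHCSDesign(n=120, k=40, r=100, T=1.0)

x = np.sort(sample(design.n, params, rng=7))
cs = apply_ghcs(x, design)
print(f"censoring outcome: case {cs.case}, m = {cs.m} failures observed, "
      f"stopped at T* = {cs.t_star:.4f} (D = {cs.D} failures before T = {design.T})")

beta_hat = mle_beta(cs)
stats = sufficient_stats(cs, beta_hat)
lam_hat = mle_lambda(stats)
print(f"profile MLE: beta_hat = {beta_hat:.4f} (truth 1), lambda_hat = m/Q = {lam_hat:.4f} (truth 2)")
print("Q is the 'total transformed time on test': the sufficient statistic that, "
      "with m, carries all the information about lambda.")
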