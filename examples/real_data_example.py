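"""Worked example: 60 electrical-appliance failure times (thousands of cycles).

Applies the generalized Type-I hybrid censoring design
(n, (r, k), T) = (60, (18, 15), 2), then reports ML, Bayes and E-Bayes
estimates of lam and the reliability at t = 1 (i.e. 1000 cycles), at the
profile-ML shape parameter.
"""

from chen_ghcs import (
    GammaPrior,
    GHCSDesign,
    HyperPrior,
    Loss,
    SE,
    apply_ghcs,
    bayes_lambda,
    bayes_reliability,
    credible_interval,
    ebayes_lambda,
    load_electrical,
    mle_beta,
    mle_lambda,
    posterior,
    sufficient_stats,
)

times = load_electrical()
design = GHCSDesign(n=60, k=15, r=18, T=2.0)
cs = apply_ghcs(times, design)
print(f"design (n, (r,k), T) = (60, (18,15), 2) -> case {cs.case}: "
      f"m = {cs.m} failures, stopped at T* = x_(18:60) = {cs.t_star}")

beta_hat = mle_beta(cs)
stats = sufficient_stats(cs, beta_hat, t=1.0)
print(f"profile MLE beta_hat = {beta_hat:.4f} (< 1: bathtub-shaped hazard)")
print(f"lambda_MLE = m/Q = {mle_lambda(stats):.4f}")

prior = GammaPrior(0.6119, 0.1523)
post = posterior(stats, prior)
linex = Loss("linex", 1.5)
lo, hi = credible_interval(post)
print(f"lambda_BS = {bayes_lambda(post, SE):.4f}, lambda_BL = {bayes_lambda(post, linex):.4f}, "
      f"95% CRI = ({lo:.4f}, {hi:.4f})")
print(f"R_BS(t=1) = {bayes_reliability(1.0, post, beta_hat, SE):.4f} "
      "(posterior probability a unit survives 1000 cycles)")
for c in (0.25, 0.5, 1.0, 1.5):
    print(f"  c = {c:4.2f}: lambda_EBS1 = {ebayes_lambda(stats, HyperPrior(1, c), SE):.4f}")
print("The E-Bayes estimate decreases as the hyperprior bound c grows.")
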