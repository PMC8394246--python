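"""Scaled replicate study: Monte-Carlo performance of the estimators.

Reruns the first study configuration (lam = 4.37, beta = 1, n = 50,
(r, k) = (40, 30), T = 0.2) at 500 replicates and prints replicate means,
empirical MSEs, posterior risks and credible-interval summaries.
"""

from chen_ghcs import ChenParams, GammaPrior, GHCSDesign, SimConfig, run_study

config = SimConfig(
    true_params=ChenParams(4.37, 1.0),
    design=GHCSDesign(n=50, k=30, r=40, T=0.2),
    prior=GammaPrior(0.6119, 0.1523),
    c=1.0,
    h=1.5,
    t=0.07,
    reps=500,
    seed=42,
)
table = run_study(config)
s = table.summary.iloc[0]

print(f"{config.reps} replicates, true lambda = 4.37, R(0.07) = 0.7285")
print(f"mean lambda_BS  = {s['lambda_BS']:.4f}   (empirical MSE {s['MSE_lambda_BS']:.4f}, "
      f"posterior risk {s['risk_lambda_BS']:.4f})")
print(f"mean lambda_BL  = {s['lambda_BL']:.4f}   (posterior risk {s['risk_lambda_BL']:.4f}, "
      "> BS risk: the posterior mean minimises quadratic risk)")
print(f"mean lambda_EBS1 = {s['lambda_EBS1']:.4f}  (E-MSE {s['EMSE_lambda_SE']:.4f}, "
      "< BS risk: hyperprior averaging shrinks risk)")
print(f"mean R_BS(0.07) = {s['R_BS']:.5f}")
print(f"mean 95% CRI    = ({s['cri_min']:.4f}, {s['cri_max']:.4f}), length {s['cri_length']:.4f}")
print(f"mean observed failures m = {s['mean_m']:.1f} of n = 50")
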