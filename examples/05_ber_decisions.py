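"""Bioactivity exposure ratios, consistent decision thresholds, and evaluation.

The BER distribution for a scenario is POD / Cmax with Cmax drawn from the
fitted predictive distribution at the relevant PBK level. A scenario is called
low risk when Prob(BER > 1) exceeds a level-specific confidence threshold —
equivalently, when the BER point estimate exceeds a level-specific threshold
BER. Lower PBK levels need larger thresholds so that a low-risk call is
unlikely (here, <= 10% chance) to be overturned when the PBK model is refined.
"""

from toxber import (
    McmcConfig,
    SyntheticConfig,
    derive_consistent_thresholds,
    evaluate_decisions,
    fit_error_model,
    generate_portfolio,
    point_biserial_distribution,
)

dataset, _ = generate_portfolio(SyntheticConfig(seed=42))
fit = fit_error_model(dataset, mcmc=McmcConfig(chains=4, warmup=800, samples=800, seed=3))

model = derive_consistent_thresholds(fit, top_level_p=0.95, overturn_prob=0.1)
print("prototype decision model (low risk iff BER point estimate > threshold):")
for lev in ("L1", "L2", "L3"):
    print(f"  {lev}: threshold BER {model.threshold_ber[lev]:7.1f}   "
          f"p_threshold {model.p_threshold[lev]:.3f}")

evaluation = evaluate_decisions(fit, dataset, model)
print("\nper-level performance against the benchmark risk labels:")
for lev in ("L1", "L2", "L3"):
    print(f"  {lev}: utility {evaluation[lev]['utility']:.2f} "
          f"(low-risk scenarios correctly identified), "
          f"protectiveness {evaluation[lev]['protectiveness']:.2f} "
          f"(high-risk scenarios not called low risk)")

pb = point_biserial_distribution(fit, dataset)
lo, hi = pb["interval_95"]
print(f"\npoint-biserial correlation of log10 BER with the high-risk label: "
      f"{pb['mean']:.2f} (95% interval {lo:.2f} to {hi:.2f})")
print("A strongly negative value means smaller safety margins go with high-risk exposures.")
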