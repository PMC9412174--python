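"""Generate a synthetic benchmark portfolio of chemical-exposure scenarios.

Each scenario has a true (unobserved) population-average plasma Cmax, PBK model
estimates of it at up to three parameterization levels (L1 in silico only,
L2 + in vitro, L3 + clinical calibration), sometimes a clinically measured
value, one minimum in vitro point of departure (POD), and a benchmark risk
label derived from the true bioactivity exposure ratio POD / Cmax.
"""

from toxber import SyntheticConfig, generate_portfolio

cfg = SyntheticConfig(seed=42)
dataset, truth = generate_portfolio(cfg)

print(f"{len(dataset)} scenarios, "
      f"{sum(r.zhat_clinical is not None for r in dataset.scenarios)} with a clinical measurement, "
      f"{sum(r.zhat_L3 is None for r in dataset.scenarios)} missing the L3 estimate\n")

print(dataset.scenarios_frame().head(5).to_string(index=False))
print("\nGround truth for the same rows (log10 uM true Cmax, true BER, label):")
print(truth[["chemical", "zeta", "true_ber", "risk_label"]].head(5).to_string(index=False))
print("\nA true BER below 1 means the plasma Cmax exceeds the most sensitive in",
      "vitro POD, which is what the 'high' benchmark label encodes here.")
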