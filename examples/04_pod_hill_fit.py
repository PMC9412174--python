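"""In vitro pharmacological profiling: screening rules and Bayesian Hill fits.

A chemical is screened against a target panel at a fixed concentration (10 uM
by default, 100 uM when cytotoxicity only appears above 100 uM). Targets with
specific binding above 50% of control are followed up with an 8-concentration
curve, from which a Bayesian Hill fit yields the IC50 posterior; the minimum
EC50/IC50 across targets is the platform POD.
"""

import numpy as np

from toxber import (
    PODRecord,
    fit_hill,
    generate_hill_curves,
    min_platform_pod,
    screening_followup,
    select_screening_concentration,
)

print("screening concentration, cytotoxicity first seen at 250 uM:",
      select_screening_concentration(250.0), "uM")
print("screening concentration, cytotoxicity first seen at 30 uM:",
      select_screening_concentration(30.0), "uM")
print("follow up 62% specific binding?", screening_followup(62.0))
print("follow up 48% specific binding?", screening_followup(48.0))

curves = generate_hill_curves(
    {"xc50_um": 5.0, "slope": 1.0, "mode": "antagonist"},
    {"replicates": 2, "noise_sd": 5.0},
    seed=7,
)
result = fit_hill(curves)
lo, hi = np.quantile(result.xc50_draws, [0.05, 0.95])
print(f"\ntrue IC50 5.0 uM -> posterior median {result.point_estimate:.2f} uM, "
      f"90% interval ({lo:.2f}, {hi:.2f})")

pods = [
    PODRecord(chemical_name="example", platform="IPP", pod_um=result.point_estimate),
    PODRecord(chemical_name="example", platform="CSP_BIFROST", pod_um=1.8),
    PODRecord(chemical_name="example", platform="HTTr_HepG2_BIFROST", pod_um=0.9),
]
print(f"minimum POD across platforms: {min_platform_pod(pods, 'example'):.2f} uM")
print("This minimum POD is the numerator of the bioactivity exposure ratio.")
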