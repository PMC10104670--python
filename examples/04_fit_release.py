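"""Fit the release model to a noisy synthetic assay and quantify uncertainty.

Generates triplicate cumulative-release data on the in-vitro sampling
schedule (daily for 4 days, then days 7/14/21/28), fits the three phase
parameters by bounded linear least squares, and brackets them with a
seeded residual bootstrap.
"""

from depotpk import (
    ReleaseNoiseModel,
    bootstrap_ci,
    default_release_params,
    generate_release_data,
)

true = default_release_params("6.5 um")
data = generate_release_data(
    true, noise=ReleaseNoiseModel(sd_additive=0.01, seed=11), n_replicates=3
)
fit = bootstrap_ci(data, n_boot=1000, seed=7)

p = fit.params
print(f"burst fraction:   {p.burst_fraction:.4f}  (true 0.130)")
print(f"phase-2 fraction: {p.phase2_fraction:.4f}  (true 0.150)")
print(f"sustained rate:   {p.sustained_rate:.5f}/day  (true 0.00400)")
for name, (lo, hi) in fit.ci.items():
    print(f"  95% CI {name}: [{lo:.4f}, {hi:.4f}]")
print("each interval should (and here does) bracket the generating value")
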