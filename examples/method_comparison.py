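"""Compare a digital pipeline against tape measurements on a cohort.

Simulates 35 subjects whose digital readings carry a +2 cm systematic
offset over the tape values, then prints the per-site comparison row:
the group-mean difference Δ (DA − CA) with significance stars, regression
R² and RMSE, and the Bland–Altman bias with limits of agreement.
"""

import numpy as np

from anthroscan import PairedSample, compare_methods

rng = np.random.default_rng(0)
samples = []
for site, scale in (("waist", 85.0), ("hip", 100.0), ("ankle_left", 22.0)):
    ca = rng.normal(scale, 0.12 * scale, 35)
    da = ca + rng.normal(2.0, 1.0, 35)  # +2 cm systematic digital offset
    samples.append(PairedSample(ca, da, site=site, device="simulated"))

report = compare_methods(samples)
cols = ["site", "n", "ca_mean", "da_mean", "delta_mean", "stars",
        "r2", "rmse", "ba_bias", "ba_lo", "ba_hi", "ba_slope"]
print(report[cols].to_string(index=False,
                             float_format=lambda v: f"{v:.2f}"))
print("\nΔ > 0 with *** : the simulated scanner reads systematically high;")
print("R² near 1 and narrow limits of agreement: it tracks the tape well.")
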