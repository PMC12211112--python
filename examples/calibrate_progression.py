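"""Calibrate the latent-progression rate against a resectability target.

theta is the per-month probability that an undetected, still-operable
recurrence becomes chemotherapy-only. It is the one structural parameter
the source data cannot identify directly, so it is calibrated by bisection
until a reference schedule reproduces an observed resectability of the
initial recurrence.
"""

import survcea as sc
from survcea.microsim import SimSettings

params = sc.load_params()
jsccr = sc.bundled_strategies()["jsccr"]

for target in (0.461, 0.40, 0.30):
    cal = sc.calibrate_theta(
        params, jsccr, target, SimSettings(n_trials=30_000, seed=17), tol=2e-3
    )
    print(f"target {target:.3f}: theta*={cal.theta:.5f} achieved={cal.achieved:.4f} "
          f"iterations={cal.iterations} achievable range="
          f"[{cal.achievable_range[0]:.3f}, {cal.achievable_range[1]:.3f}]")

print("\n(at the shipped target 0.461 theta pins to 0: the fixed 38% resection")
print(" rate plus the 19.2%/5yr conversion pathway already reproduce it; lower")
print(" targets are met by interior theta values)")
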