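"""Speed-dependent spatiotemporal gait measures and curve fits.

Stance and stride time decay exponentially with speed (y0 + a e^(-b x)),
stride distance grows linearly; swing time is nearly speed-independent.
Fits are per condition over hindlimb steps with 95% prediction
intervals; duty cycle and mean speed summarize each condition.
"""

import sys
from pathlib import Path

import json
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from quadgait import pipeline as pl
from quadgait.stats import fit_speed_curve

cohort = common.load_or_generate()
spa = pl.cohort_spatiotemporal(cohort.footfalls)
hind = spa[spa["limb"].isin(["LH", "RH"])]
common.RESULTS.mkdir(exist_ok=True)
spa.to_csv(common.RESULTS / "spatiotemporal_table.csv", index=False)

fits = {}
for cond, grp in hind.groupby("condition"):
    x = grp["speed_cm_s"]
    stance = fit_speed_curve(x, grp["stance_s"], "exponential_decay")
    stride = fit_speed_curve(x, grp["stride_s"], "exponential_decay")
    dist = fit_speed_curve(x, grp["stride_distance_cm"], "linear")
    fits[cond] = {
        "n_steps": int(len(grp)),
        "stance": {"coefficients": stance.coefficients, "r2": round(stance.r_squared, 3)},
        "stride": {"coefficients": stride.coefficients, "r2": round(stride.r_squared, 3)},
        "stride_distance": {"coefficients": dist.coefficients, "r2": round(dist.r_squared, 3)},
        "mean_swing_s": round(float(grp["swing_s"].mean()), 3),
        "mean_stance_s": round(float(grp["stance_s"].mean()), 3),
        "mean_duty_cycle": round(float(grp["duty_cycle"].mean()), 3),
        "mean_speed_cm_s": round(float(grp["speed_cm_s"].mean()), 1),
    }
    print(f"{cond}: n = {len(grp)} steps")
    print(f"  stance  = {stance.coefficients[0]:.3f} + {stance.coefficients[1]:.3f}"
          f"*exp(-{stance.coefficients[2]:.4f}*speed)   R^2 = {stance.r_squared:.3f}")
    print(f"  duty cycle {fits[cond]['mean_duty_cycle']:.3f}, "
          f"swing {fits[cond]['mean_swing_s']:.3f} s, "
          f"speed {fits[cond]['mean_speed_cm_s']:.1f} cm/s")

with open(common.RESULTS / "speed_curve_fits.json", "w", encoding="utf-8") as fh:
    json.dump(fits, fh, indent=2)
print(f"\nwrote {common.RESULTS / 'speed_curve_fits.json'}")
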