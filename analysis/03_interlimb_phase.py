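"""Interlimb phase and irregularity classification across conditions.

For each limb pair the phase of every step is transformed to the linear
scale, thresholds are derived from the uninjured control condition
(mean +/- 2 SD), and the proportion of irregular steps in every other
condition is compared to control with the two-proportion z-test
(unpooled variance).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from quadgait import pipeline as pl
from quadgait.stats import two_proportion_z

cohort = common.load_or_generate()
phase = pl.cohort_phase_table(cohort.footfalls)
phase, thresholds = pl.attach_irregularity(phase, "uninjured_control")
common.RESULTS.mkdir(exist_ok=True)
phase.to_csv(common.RESULTS / "phase_table.csv", index=False)

print("2-SD thresholds on the linear scale (from uninjured control):")
for pair, thr in thresholds.items():
    print(f"  {pair:14s} mean {thr.control_mean:.3f}  sd {thr.control_sd:.3f}  "
          f"bounds [{thr.lower:.3f}, {thr.upper:.3f}]")

rows = []
print("\nirregular steps vs uninjured control (unpooled z):")
for pair, sub in phase.groupby("pair"):
    ctrl = sub[sub["condition"] == "uninjured_control"]
    k1, n1 = int(ctrl["irregular"].sum()), len(ctrl)
    for cond, grp in sub.groupby("condition"):
        k2, n2 = int(grp["irregular"].sum()), len(grp)
        row = {"pair": pair, "condition": cond, "k": k2, "n": n2,
               "pct": round(100 * k2 / n2, 2)}
        if cond != "uninjured_control":
            res = two_proportion_z(k1, n1, k2, n2, "unpooled")
            row.update(z=round(res.z, 2), p=res.p)
            print(f"  {pair:14s} {cond:20s} {k2:4d}/{n2:<4d} [{row['pct']:6.2f}%]  "
                  f"z = {abs(res.z):.2f}")
        rows.append(row)
pd.DataFrame(rows).to_csv(common.RESULTS / "phase_irregularity.csv", index=False)
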