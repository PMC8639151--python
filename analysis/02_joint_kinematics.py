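"""Hindlimb joint-angle kinematics: excursions and intralimb coordination.

Computes proximal (hip) and distal (ankle) angle excursions and the
proximal-to-distal peak lag per step cycle on the marker-trajectory
cohort, then contrasts injured control vs injured silenced with a paired
t-test over animal means — the pattern expected is larger excursions and
a smaller lag under silencing.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from quadgait import kinematics as kin
from quadgait import pipeline as pl
from quadgait.stats import paired_t

cohort = common.marker_cohort()
rows = []
for (cond, animal, pass_id), by_limb in cohort.markers.items():
    ff = cohort.footfalls
    events = ff[(ff["condition"] == cond) & (ff["animal"] == animal) & (ff["pass"] == pass_id)]
    cycles = pl.segment_pass(events)
    for limb in ("LH", "RH"):
        ang = kin.compute_joint_angles(by_limb[limb])
        for c in cycles[limb]:
            prox, dist = kin.angle_excursion(ang, (c.contact_s, c.next_contact_s))
            lag = kin.intralimb_lag(ang, c)
            rows.append(
                {"condition": cond, "animal": animal, "pass": pass_id, "limb": limb,
                 "proximal_excursion_deg": prox, "distal_excursion_deg": dist,
                 "intralimb_lag": lag}
            )

df = pd.DataFrame(rows)
common.RESULTS.mkdir(exist_ok=True)
df.to_csv(common.RESULTS / "kinematics_per_cycle.csv", index=False)

per_animal = df.groupby(["condition", "animal"])[
    ["proximal_excursion_deg", "distal_excursion_deg", "intralimb_lag"]
].mean()
print(per_animal.groupby("condition").mean().round(2).to_string())

a = per_animal.loc["sci_control"]
b = per_animal.loc["sci_silenced"]
for col in ("proximal_excursion_deg", "distal_excursion_deg"):
    t, dof, p = paired_t(b[col].to_numpy(), a[col].to_numpy())
    print(f"silenced - control, {col}: t({dof}) = {t:.2f}, p = {p:.4f}")
print(f"wrote {common.RESULTS / 'kinematics_per_cycle.csv'} ({len(df)} cycles)")
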