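"""Footfall-pattern gait indices across conditions.

Computes RI, CPI, PSI, and DSI per pass, averages per animal and then
per condition, and contrasts injured control vs injured silenced with
paired t-tests over animal means — silencing after injury should raise
RI/CPI/PSI and lower DSI.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from quadgait import pipeline as pl
from quadgait.stats import paired_t

cohort = common.load_or_generate()
idx = pl.cohort_index_table(cohort.footfalls)
common.RESULTS.mkdir(exist_ok=True)
idx.to_csv(common.RESULTS / "index_table.csv", index=False)

group = pl.aggregate_indices(idx)
group.to_csv(common.RESULTS / "group_indices.csv", index=False)
print(group.round(2).to_string(index=False))

per_animal = idx.groupby(["condition", "animal"])[["ri", "cpi", "psi", "dsi"]].mean()
print("\ninjured silenced vs injured control (paired over animals):")
for metric in ("ri", "cpi", "psi", "dsi"):
    a = per_animal.loc["sci_control", metric].to_numpy()
    b = per_animal.loc["sci_silenced", metric].to_numpy()
    t, dof, p = paired_t(b, a)
    print(f"  {metric.upper():3s}: {a.mean():6.2f} -> {b.mean():6.2f}   "
          f"t({dof}) = {t:5.2f}, p = {p:.4f}")
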