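"""Generate the synthetic four-condition cohort used by the later scripts.

Conditions: uninjured and spinal-contused animals, each with and without
conditional silencing of long ascending propriospinal neurons.  Writes
footfall and swim event tables under results/synthetic/ and prints the
cohort bookkeeping.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

cohort = common.load_or_generate()
ff = cohort.footfalls

print(f"seed {common.SEED}; {len(cohort.config.conditions)} conditions, "
      f"{cohort.config.n_animals} animals x {cohort.config.passes_per_animal} passes")
summary = ff.groupby("condition").agg(
    steps=("contact_s", "size"),
    dorsal=("step_type", lambda s: (s == "dorsal").sum()),
)
print(summary.to_string())
print(f"\ntables written under {common.SYNTH}")
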