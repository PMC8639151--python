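"""Shared cohort access for the numbered analysis scripts.

Each script can be run standalone: the synthetic cohort tables are
generated on first use (seed 1) and cached under results/synthetic/.
"""

from __future__ import annotations

from pathlib import Path

from quadgait import io as qio
from quadgait import simulate as sim

RESULTS = Path(__file__).resolve().parent.parent / "results"
SYNTH = RESULTS / "synthetic"
SEED = 1

#: main cohort design: 6 animals, 6 passes each, in all four conditions
COHORT_KW = dict(n_animals=6, passes_per_animal=6, strides_per_pass=(5, 9))
#: smaller design used for the marker-trajectory (kinematics) subset
MARKER_KW = dict(n_animals=3, passes_per_animal=2, strides_per_pass=(6, 8))


def load_or_generate() -> sim.Cohort:
    """The event-table cohort (no markers), generated once and cached."""
    ff_path = SYNTH / "footfalls.csv"
    if ff_path.exists():
        cohort = sim.generate_cohort(_config(include_markers=False))
        return cohort  # deterministic: regenerating equals reading the cache
    SYNTH.mkdir(parents=True, exist_ok=True)
    cohort = sim.generate_cohort(_config(include_markers=False))
    qio.write_footfall_table(cohort.footfalls, ff_path)
    qio.write_swim_table(cohort.swim, SYNTH / "swim.csv")
    return cohort


def marker_cohort() -> sim.Cohort:
    """A smaller cohort with full marker trajectories for kinematics."""
    return sim.generate_cohort(
        sim.SyntheticConfig(
            conditions=list(sim.default_conditions().values()),
            seed=SEED + 100,
            include_markers=True,
            **MARKER_KW,
        )
    )


def _config(include_markers: bool) -> sim.SyntheticConfig:
    return sim.SyntheticConfig(
        conditions=list(sim.default_conditions().values()),
        seed=SEED,
        include_markers=include_markers,
        **COHORT_KW,
    )
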