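"""End-to-end analysis: segmentation -> phase -> classification ->
indices -> statistics, over event tables or a generated cohort.

The pipeline consumes a four-limb footfall event table (and optionally a
swim peak-extension table), computes per-pass step cycles and phase
observations for the requested limb pairs, derives 2-SD irregularity
thresholds from the designated control condition, classifies every
phase, computes the per-pass gait indices, and summarizes group
contrasts with two-proportion z-tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import coordination as coord
from . import events as ev
from . import indices as idx
from . import io as qio
from . import stats as st
from .types import FORELIMBS, HINDLIMBS, LIMBS, StepCycle

logger = logging.getLogger("quadgait")

__all__ = [
    "segment_pass",
    "pass_phases",
    "cohort_phase_table",
    "cohort_index_table",
    "cohort_spatiotemporal",
    "swim_phase_table",
    "attach_irregularity",
    "aggregate_indices",
    "run_pipeline",
]

#: (reference limb, test limb) per overground pair
PAIR_LIMBS = {
    "hindlimb": ("LH", "RH"),
    "forelimb": ("LF", "RF"),
    "homolateral": ("LH", "LF"),
    "heterolateral": ("LH", "RF"),
}


def segment_pass(events: pd.DataFrame) -> Dict[str, List[StepCycle]]:
    """Per-limb step cycles from one pass's event table."""
    out: Dict[str, List[StepCycle]] = {}
    for limb in LIMBS:
        sub = events[events["limb"] == limb]
        out[limb] = ev.cycles_from_events(sub, limb) if len(sub) >= 2 else []
    return out


def pass_phases(
    cycles_by_limb: Mapping[str, Sequence[StepCycle]],
    events: pd.DataFrame,
    pairs: Sequence[str],
) -> List[dict]:
    """Phase observations for the requested pairs within one pass.

    A phase observation is labelled dorsal when either the reference
    cycle or the contributing test step is dorsal.
    """
    rows: List[dict] = []
    for pair in pairs:
        ref_limb, test_limb = PAIR_LIMBS[pair]
        ref_cycles = cycles_by_limb.get(ref_limb, [])
        test = events[events["limb"] == test_limb]
        if not ref_cycles or len(test) == 0:
            continue
        obs = coord.interlimb_phase(
            ref_cycles,
            test["contact_s"].to_numpy(),
            pair,
            test["step_type"].tolist(),
        )
        for o in obs:
            ref_type = ref_cycles[o.reference_index].step_type
            step_type = "dorsal" if "dorsal" in (ref_type, o.step_type) else "plantar"
            rows.append(
                {
                    "pair": pair,
                    "raw_phase": o.raw_phase,
                    "linear_phase": o.linear_phase,
                    "step_type": step_type,
                    "multi_step": o.multi_step,
                    "reference_index": o.reference_index,
                }
            )
    return rows


def _group_cols(df: pd.DataFrame) -> List[str]:
    cols = [c for c in ("condition", "animal", "pass") if c in df.columns]
    if not cols:
        raise ValueError("table needs at least one of condition/animal/pass columns")
    return cols


def cohort_phase_table(
    footfalls: pd.DataFrame, pairs: Sequence[str] = tuple(PAIR_LIMBS)
) -> pd.DataFrame:
    """Phase observations for every pass in a cohort footfall table."""
    gcols = _group_cols(footfalls)
    frames = []
    for key, events in footfalls.groupby(gcols):
        cycles = segment_pass(events)
        rows = pass_phases(cycles, events, pairs)
        if not rows:
            continue
        df = pd.DataFrame(rows)
        for c, v in zip(gcols, key if isinstance(key, tuple) else (key,)):
            df.insert(0, c, v)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=gcols + ["pair", "raw_phase", "linear_phase", "step_type", "multi_step"]
        )
    return pd.concat(frames, ignore_index=True)


def swim_phase_table(swim: pd.DataFrame) -> pd.DataFrame:
    """Swim-pair phase observations from a peak-extension event table."""
    gcols = _group_cols(swim)
    frames = []
    for key, events in swim.groupby(gcols):
        ref = events[events["limb"] == coord.REFERENCE_LIMBS["swim"]]
        near = events[events["limb"] != coord.REFERENCE_LIMBS["swim"]]
        cycles = coord.stroke_cycles(ref["peak_s"].to_numpy())
        if not cycles or len(near) == 0:
            continue
        obs = coord.swim_phase(near["peak_s"].to_numpy(), cycles)
        df = pd.DataFrame(
            [
                {
                    "pair": "swim",
                    "raw_phase": o.raw_phase,
                    "linear_phase": o.linear_phase,
                    "step_type": "plantar",
                    "multi_step": o.multi_step,
                }
                for o in obs
            ]
        )
        for c, v in zip(gcols, key if isinstance(key, tuple) else (key,)):
            df.insert(0, c, v)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=gcols + ["pair", "raw_phase", "linear_phase"])
    return pd.concat(frames, ignore_index=True)


def attach_irregularity(
    phase_df: pd.DataFrame, control_label: str
) -> Tuple[pd.DataFrame, Dict[str, coord.IrregularityThreshold]]:
    """Derive per-pair thresholds from the control condition and classify.

    Control linear-phase values are pooled across animals of the control
    condition.  Returns the phase table with an ``irregular`` column and
    the per-pair thresholds.
    """
    if "condition" not in phase_df.columns:
        raise ValueError("phase table needs a 'condition' column")
    out = phase_df.copy()
    out["irregular"] = False
    thresholds: Dict[str, coord.IrregularityThreshold] = {}
    for pair, sub in phase_df.groupby("pair"):
        control = sub.loc[sub["condition"] == control_label, "linear_phase"]
        if len(control) < 3:
            logger.warning("pair %s: too few control values, skipping", pair)
            continue
        thr = coord.control_threshold(control.to_numpy(), pair)
        thresholds[pair] = thr
        flags, *_ = coord.classify_irregular(sub["linear_phase"].to_numpy(), thr)
        out.loc[sub.index, "irregular"] = flags
    return out, thresholds


def cohort_index_table(footfalls: pd.DataFrame) -> pd.DataFrame:
    """Per-pass RI/CPI/PSI/DSI for a cohort footfall table."""
    gcols = _group_cols(footfalls)
    rows = []
    for key, events in footfalls.groupby(gcols):
        cycles = segment_pass(events)
        seq = ev.footfall_sequence_from_events(events)
        hind = list(cycles["LH"]) + list(cycles["RH"])
        rep = idx.pass_indices(seq, hind)
        row = dict(zip(gcols, key if isinstance(key, tuple) else (key,)))
        row.update(asdict(rep))
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_indices(index_df: pd.DataFrame) -> pd.DataFrame:
    """Animal averages first, then the group average per condition.

    Matches the reporting convention in which group means are means of
    per-animal mean indices, not of pooled passes.
    """
    metrics = ["ri", "cpi", "psi", "dsi"]
    per_animal = (
        index_df.groupby(["condition", "animal"])[metrics].mean().reset_index()
    )
    group = per_animal.groupby("condition")[metrics].agg(["mean", "std"])
    group.columns = [f"{m}_{s}" for m, s in group.columns]
    return group.reset_index()


def cohort_spatiotemporal(footfalls: pd.DataFrame) -> pd.DataFrame:
    """One row per complete step cycle with its spatiotemporal measures."""
    gcols = _group_cols(footfalls)
    rows = []
    for key, events in footfalls.groupby(gcols):
        for limb, cycles in segment_pass(events).items():
            for c in cycles:
                row = dict(zip(gcols, key if isinstance(key, tuple) else (key,)))
                row.update(
                    {
                        "limb": limb,
                        "swing_s": c.swing_s,
                        "stance_s": c.stance_s,
                        "stride_s": c.stride_s,
                        "stride_distance_cm": c.stride_distance_cm,
                        "speed_cm_s": c.instantaneous_speed_cm_s,
                        "duty_cycle": c.duty_cycle,
                        "stride_frequency_hz": c.stride_frequency_hz,
                        "step_type": c.step_type,
                    }
                )
                rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: qio.RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Emits per-pass phase and index tables, group summaries, and a JSON
    summary with thresholds, test results, and provenance (seed, config
    hash).  Returns the summary dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = qio.config_hash(asdict(config))

    if config.footfall_path is None:
        raise ValueError("run_pipeline requires a footfall table path")
    footfalls = qio.read_footfall_table(config.footfall_path)
    if "condition" not in footfalls.columns:
        footfalls = footfalls.assign(condition="all")

    phase_df = cohort_phase_table(footfalls, config.pairs)
    phase_df, thresholds = attach_irregularity(phase_df, config.control_label)
    index_df = cohort_index_table(footfalls)
    spatio_df = cohort_spatiotemporal(footfalls)

    swim_df = None
    if config.swim_path is not None:
        swim_raw = qio.read_swim_table(config.swim_path)
        if "condition" not in swim_raw.columns:
            swim_raw = swim_raw.assign(condition="all")
        swim_df = swim_phase_table(swim_raw)

    # proportion of irregular steps: every condition vs control, per pair
    tests = []
    for pair, sub in phase_df.groupby("pair"):
        ctrl = sub[sub["condition"] == config.control_label]
        if len(ctrl) == 0:
            continue
        k1, n1 = int(ctrl["irregular"].sum()), len(ctrl)
        for cond, grp in sub.groupby("condition"):
            if cond == config.control_label:
                continue
            k2, n2 = int(grp["irregular"].sum()), len(grp)
            try:
                res = st.two_proportion_z(k1, n1, k2, n2, config.variance_variant)
            except ValueError:
                continue
            tests.append(
                {
                    "pair": pair,
                    "comparison": f"{config.control_label} vs {cond}",
                    **asdict(res),
                }
            )

    phase_df.to_csv(out_dir / "phase_table.csv", index=False)
    index_df.to_csv(out_dir / "index_table.csv", index=False)
    spatio_df.to_csv(out_dir / "spatiotemporal_table.csv", index=False)
    if swim_df is not None:
        swim_df.to_csv(out_dir / "swim_phase_table.csv", index=False)
    group_idx = aggregate_indices(index_df)
    group_idx.to_csv(out_dir / "group_indices.csv", index=False)

    summary = {
        "provenance": {
            "seed": config.seed,
            "config_hash": cfg_hash,
            "software": "quadgait 0.1.0",
        },
        "thresholds": {
            pair: asdict(thr) for pair, thr in thresholds.items()
        },
        "proportion_tests": tests,
        "group_indices": group_idx.to_dict(orient="records"),
        "n_phase_observations": int(len(phase_df)),
        "n_step_cycles": int(len(spatio_df)),
    }
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
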