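"""Step-cycle segmentation and four-limb footfall assembly.

A *step cycle* runs from one initial paw contact to the next initial
contact of the same limb: stance (contact -> lift-off) plus swing
(lift-off -> next contact).  Stride distance is the toe displacement
between consecutive contacts, and a step's instantaneous speed is stride
distance over stride time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import LIMB_TIE_ORDER, StepCycle

__all__ = [
    "ContactTrace",
    "segment_step_cycles",
    "cycles_from_events",
    "spatiotemporal_summary",
    "build_footfall_sequence",
    "DEBOUNCE_FRAMES",
]

#: contact-state runs shorter than this many frames are treated as
#: digitization noise and merged into the surrounding state
DEBOUNCE_FRAMES = 3


@dataclass
class ContactTrace:
    """Per-frame ground-contact state of one limb."""

    limb: str
    time_s: np.ndarray
    contact: np.ndarray  # boolean
    toe_x_cm: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.contact = np.asarray(self.contact, dtype=bool)
        self.toe_x_cm = np.asarray(self.toe_x_cm, dtype=float)
        if not (self.time_s.shape == self.contact.shape == self.toe_x_cm.shape):
            raise ValueError("trace arrays must share one length")
        if self.time_s.size > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")


def _debounce(flags: np.ndarray, min_run: int = DEBOUNCE_FRAMES) -> np.ndarray:
    """Merge contact-state runs shorter than *min_run* into their context."""
    out = flags.copy()
    if out.size == 0:
        return out
    # iterate until stable; short runs can cascade after a merge
    changed = True
    while changed:
        changed = False
        edges = np.flatnonzero(np.diff(out.astype(np.int8))) + 1
        bounds = np.concatenate([[0], edges, [out.size]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            if 0 < s and e < out.size and (e - s) < min_run:
                out[s:e] = out[s - 1]
                changed = True
                break
    return out


def segment_step_cycles(
    trace: ContactTrace,
    step_types: Optional[Sequence[str]] = None,
    debounce: int = DEBOUNCE_FRAMES,
) -> List[StepCycle]:
    """Segment a per-frame contact trace into complete step cycles.

    Contact onsets and offsets are read from the debounced flag; each
    onset->next-onset interval containing an offset becomes a
    :class:`StepCycle`.  Incomplete trailing cycles are dropped; a trace
    with fewer than two onsets yields an empty list.  ``step_types``
    optionally labels each produced cycle (plantar/dorsal), in onset
    order.
    """
    flags = _debounce(trace.contact, debounce) if debounce > 1 else trace.contact
    d = np.diff(flags.astype(np.int8))
    onsets = np.flatnonzero(d == 1) + 1
    offsets = np.flatnonzero(d == -1) + 1
    if flags[0]:
        onsets = np.concatenate([[0], onsets])
    cycles: List[StepCycle] = []
    for k in range(len(onsets) - 1):
        on, nxt = onsets[k], onsets[k + 1]
        offs = offsets[(offsets > on) & (offsets < nxt)]
        if offs.size == 0:
            continue
        st = "plantar" if step_types is None else step_types[len(cycles)]
        cycles.append(
            StepCycle(
                limb=trace.limb,
                contact_s=float(trace.time_s[on]),
                liftoff_s=float(trace.time_s[offs[0]]),
                next_contact_s=float(trace.time_s[nxt]),
                stride_distance_cm=float(
                    abs(trace.toe_x_cm[nxt] - trace.toe_x_cm[on])
                ),
                step_type=st,
            )
        )
    return cycles


def cycles_from_events(events: pd.DataFrame, limb: str) -> List[StepCycle]:
    """Build step cycles from an event table of one limb.

    *events* needs columns ``contact_s, liftoff_s, toe_x_cm, step_type``;
    rows are sorted by contact time.  Cycles whose lift-off does not fall
    strictly inside the contact->next-contact interval (overlapping
    double contacts) are dropped.  The trailing contact has no successor
    and never forms a cycle.
    """
    ev = events.sort_values("contact_s", kind="mergesort").reset_index(drop=True)
    cycles: List[StepCycle] = []
    for i in range(len(ev) - 1):
        c = float(ev.loc[i, "contact_s"])
        lo = float(ev.loc[i, "liftoff_s"])
        nxt = float(ev.loc[i + 1, "contact_s"])
        if not (c < lo < nxt):
            continue
        cycles.append(
            StepCycle(
                limb=limb,
                contact_s=c,
                liftoff_s=lo,
                next_contact_s=nxt,
                stride_distance_cm=float(
                    abs(ev.loc[i + 1, "toe_x_cm"] - ev.loc[i, "toe_x_cm"])
                ),
                step_type=str(ev.loc[i, "step_type"]),
            )
        )
    return cycles


def spatiotemporal_summary(cycles: Sequence[StepCycle]) -> Dict[str, float]:
    """Arithmetic means of the spatiotemporal measures over cycles.

    Speed is the mean of per-step instantaneous speeds, matching how
    pass-average speed is reported.
    """
    if len(cycles) == 0:
        raise ValueError("spatiotemporal summary needs at least one cycle")
    return {
        "n_steps": float(len(cycles)),
        "swing_s": float(np.mean([c.swing_s for c in cycles])),
        "stance_s": float(np.mean([c.stance_s for c in cycles])),
        "stride_s": float(np.mean([c.stride_s for c in cycles])),
        "stride_distance_cm": float(np.mean([c.stride_distance_cm for c in cycles])),
        "speed_cm_s": float(np.mean([c.instantaneous_speed_cm_s for c in cycles])),
        "duty_cycle": float(np.mean([c.duty_cycle for c in cycles])),
        "stride_frequency_hz": float(np.mean([c.stride_frequency_hz for c in cycles])),
    }


def build_footfall_sequence(
    cycles_by_limb: Mapping[str, Sequence[StepCycle]],
    extra_contacts: Optional[Mapping[str, Sequence[tuple]]] = None,
) -> pd.DataFrame:
    """Merge per-limb contact onsets into one time-ordered footfall sequence.

    Returns a DataFrame with columns ``time_s, limb, step_type``.  Ties at
    identical times resolve in the fixed order LH < RH < LF < RF so the
    downstream pattern matching is deterministic.  ``extra_contacts`` may
    supply trailing ``(time_s, step_type)`` contacts that did not form a
    complete cycle but are still paw placements.
    """
    rows = []
    for limb, cycles in cycles_by_limb.items():
        for c in cycles:
            rows.append({"time_s": c.contact_s, "limb": limb, "step_type": c.step_type})
    if extra_contacts:
        for limb, items in extra_contacts.items():
            for t, st in items:
                rows.append({"time_s": float(t), "limb": limb, "step_type": st})
    if not rows:
        return pd.DataFrame(columns=["time_s", "limb", "step_type"])
    df = pd.DataFrame(rows)
    df["_tie"] = df["limb"].map(LIMB_TIE_ORDER)
    df = df.sort_values(["time_s", "_tie"], kind="mergesort").drop(columns="_tie")
    return df.reset_index(drop=True)


def footfall_sequence_from_events(events: pd.DataFrame) -> pd.DataFrame:
    """Footfall sequence straight from a four-limb event table.

    Uses every contact (including trailing ones that form no complete
    cycle), keeping the deterministic tie order.
    """
    df = events.rename(columns={"contact_s": "time_s"})[
        ["time_s", "limb", "step_type"]
    ].copy()
    df["_tie"] = df["limb"].map(LIMB_TIE_ORDER)
    df = df.sort_values(["time_s", "_tie"], kind="mergesort").drop(columns="_tie")
    return df.reset_index(drop=True)
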