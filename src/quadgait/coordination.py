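"""Interlimb and swim phase, the circular->linear transform, and
classification of steps against control-derived 2-SD thresholds.

*Phase* is the fraction of the reference limb's stride cycle at which the
test limb makes initial contact: 0 (or 1) is synchrony, 0.5 strict
alternation.  To remove lead-limb preference, raw circular values are
reflected onto a linear scale — [0.5, 1] for the alternating pairs
(left-right hindlimb, left-right forelimb, homolateral hindlimb-forelimb,
and the swim pair) and [0, 0.5] for the nominally synchronous
heterolateral pair.  A step is *irregular* when its linear phase falls
strictly more than 2 SD from the control mean, with mean and SD computed
on the linear scale from the designated control condition.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .types import (
    ALTERNATING_PAIRS,
    SYNCHRONOUS_PAIRS,
    IrregularityThreshold,
    PhaseObservation,
    StepCycle,
)

__all__ = [
    "interlimb_phase",
    "transform_phase",
    "control_threshold",
    "classify_irregular",
    "swim_phase",
    "stroke_cycles",
    "REFERENCE_LIMBS",
]

#: reference limb per pair: the left hindlimb anchors the hindlimb pair
#: and both hindlimb-forelimb pairs; the left forelimb anchors the
#: forelimb pair; the right hindlimb is the swim reference stroke limb.
REFERENCE_LIMBS = {
    "hindlimb": "LH",
    "forelimb": "LF",
    "homolateral": "LH",
    "heterolateral": "LH",
    "swim": "RH",
}


def transform_phase(raw: float, pair: str) -> float:
    """Reflect a raw circular phase onto the pair's linear scale.

    Alternating pairs map onto [0.5, 1] (``raw`` below 0.5 reflects to
    ``1 - raw``); the synchronous heterolateral pair maps onto [0, 0.5].
    The transform satisfies T(raw) = T(1 - raw) and is idempotent on its
    output range.
    """
    if not 0.0 <= raw < 1.0 + 1e-12:
        raise ValueError(f"raw phase {raw} outside [0, 1)")
    raw = float(raw) % 1.0
    if pair in ALTERNATING_PAIRS:
        return raw if raw >= 0.5 else 1.0 - raw
    if pair in SYNCHRONOUS_PAIRS:
        return raw if raw <= 0.5 else 1.0 - raw
    raise ValueError(f"unknown pair {pair!r}")


def interlimb_phase(
    reference_cycles: Sequence[StepCycle],
    test_contacts: Sequence[float],
    pair: str,
    test_step_types: Sequence[str] | None = None,
) -> List[PhaseObservation]:
    """Phase of each test-limb contact within the reference limb's cycles.

    For every reference cycle [t_i, t_{i+1}) each test contact t* inside
    it yields ``raw_phase = (t* - t_i) / (t_{i+1} - t_i)``.  Cycles with
    no test contact yield no observation; cycles with several yield one
    observation per contact, flagged ``multi_step``.
    """
    if len(reference_cycles) == 0:
        raise ValueError("at least one reference cycle required")
    contacts = np.asarray(test_contacts, dtype=float)
    order = np.argsort(contacts, kind="mergesort")
    contacts = contacts[order]
    types = (
        [test_step_types[i] for i in order]
        if test_step_types is not None
        else ["plantar"] * len(contacts)
    )

    out: List[PhaseObservation] = []
    for idx, cyc in enumerate(reference_cycles):
        t0, t1 = cyc.contact_s, cyc.next_contact_s
        if t1 <= t0:
            raise ValueError("zero-length reference stride")
        inside = np.flatnonzero((contacts >= t0) & (contacts < t1))
        multi = inside.size > 1
        for j in inside:
            raw = (contacts[j] - t0) / (t1 - t0)
            out.append(
                PhaseObservation(
                    pair=pair,
                    raw_phase=float(raw),
                    linear_phase=transform_phase(float(raw), pair),
                    reference_index=idx,
                    step_type=types[j],
                    multi_step=multi,
                )
            )
    return out


def control_threshold(
    control_values: Sequence[float], pair: str
) -> IrregularityThreshold:
    """Mean +/- 2 sample SD bounds from control linear-phase values.

    SD uses the n-1 denominator.  Bounds are clipped to the pair's valid
    linear range.  Degenerate (zero-spread) controls raise.
    """
    vals = np.asarray(control_values, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 control values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate control distribution (zero spread)")
    lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
    vmin, vmax = (0.5, 1.0) if pair in ALTERNATING_PAIRS else (0.0, 0.5)
    return IrregularityThreshold(
        pair=pair,
        control_mean=mean,
        control_sd=sd,
        lower=max(lo, vmin),
        upper=min(hi, vmax),
    )


def classify_irregular(
    values: Sequence[float], threshold: IrregularityThreshold
) -> Tuple[np.ndarray, int, int, float]:
    """Flag values strictly beyond the 2-SD control bounds.

    Returns ``(flags, k_irregular, n_total, percentage)`` with percentage
    = 100 k / n rounded to 2 decimals.  A value exactly on a bound counts
    as regular (only values strictly beyond 2 SD are irregular).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("no values to classify")
    flags = (vals < threshold.lower) | (vals > threshold.upper)
    k = int(flags.sum())
    n = int(vals.size)
    return flags, k, n, round(100.0 * k / n, 2)


def swim_phase(
    peak_times: Sequence[float],
    reference_cycles: Sequence[StepCycle],
) -> List[PhaseObservation]:
    """Nearside-hindlimb peak-extension phase within reference stroke cycles.

    Identical arithmetic to :func:`interlimb_phase` with peak-extension
    events substituting paw contacts; transformed and thresholded like
    the overground hindlimb pair.
    """
    return interlimb_phase(reference_cycles, peak_times, "swim")


def stroke_cycles(peak_times: Sequence[float], limb: str = "RH") -> List[StepCycle]:
    """Turn reference-limb peak-extension times into stroke 'cycles'.

    Swim strokes have no stance/swing split; a nominal lift-off at
    mid-cycle satisfies the cycle invariants without affecting phase
    arithmetic, which only uses the cycle boundaries.
    """
    t = np.sort(np.asarray(peak_times, dtype=float))
    out = []
    for i in range(len(t) - 1):
        if t[i + 1] <= t[i]:
            continue
        mid = 0.5 * (t[i] + t[i + 1])
        out.append(
            StepCycle(
                limb=limb,
                contact_s=float(t[i]),
                liftoff_s=float(mid),
                next_contact_s=float(t[i + 1]),
                stride_distance_cm=0.0,
            )
        )
    return out
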