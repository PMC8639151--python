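"""Footfall-pattern and step-count gait indices: RI, CPI, PSI, DSI.

The regularity index (RI) and central pattern index (CPI) score the
order of the four paws' placements against the normal step-sequence
patterns of rat gait; the plantar stepping index (PSI) and dorsal
stepping index (DSI) count placement quality after spinal cord injury.

Normal step sequence patterns
-----------------------------
The cruciate (C), alternate (A), and rotary (R) patterns, two lead
variants each::

    Ca: RF -> LF -> RH -> LH        Cb: LF -> RF -> LH -> RH
    Aa: RF -> LH -> LF -> RH        Ab: LF -> RH -> RF -> LH
    Ra: RF -> LF -> LH -> RH        Rb: LF -> RF -> RH -> LH

RI matches these six literal sequences greedily and non-overlappingly
from the start of the (dorsal-step-excluded) placement string:
``RI = 100 * (matched patterns * 4) / paw placements``.

CPI scores a rolling window of four consecutive placements, advancing
one placement at a time, so it detects double steps; dorsal steps are
included.  A window is correctly patterned when it contains each limb
exactly once in a normal cyclic order — i.e., it is some rotation of one
of the six patterns.  (A rolling window samples the periodic footfall
sequence at every offset, so correctness must be rotation-invariant for
a perfectly patterned pass to score 100.)  The six patterns cover five
of the six cyclic orders of four limbs; the remaining one — the
hindlimb-leading diagonal order LH,RF,RH,LF — is not a normal rat
pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import HINDLIMBS, StepCycle

__all__ = [
    "NORMAL_PATTERNS",
    "regularity_index",
    "central_pattern_index",
    "plantar_stepping_index",
    "dorsal_stepping_index",
    "GaitIndexReport",
    "pass_indices",
]

NORMAL_PATTERNS: Dict[str, Tuple[str, str, str, str]] = {
    "Ca": ("RF", "LF", "RH", "LH"),
    "Cb": ("LF", "RF", "LH", "RH"),
    "Aa": ("RF", "LH", "LF", "RH"),
    "Ab": ("LF", "RH", "RF", "LH"),
    "Ra": ("RF", "LF", "LH", "RH"),
    "Rb": ("LF", "RF", "RH", "LH"),
}

#: every rotation of every normal pattern (the CPI acceptance set)
_ROTATIONS = frozenset(
    tuple(p[i:] + p[:i]) for p in NORMAL_PATTERNS.values() for i in range(4)
)


def regularity_index(limbs: Sequence[str], step_types: Optional[Sequence[str]] = None):
    """RI over a footfall placement sequence, or NaN when undefined.

    Dorsal placements are excluded first; the remaining string is scanned
    left-to-right, greedily and non-overlappingly, for the six normal
    patterns.  RI = 100 * 4 * matches / placements with the denominator
    counting post-exclusion placements.  Fewer than 4 placements after
    exclusion -> NaN sentinel.
    """
    if step_types is not None:
        seq = [l for l, st in zip(limbs, step_types) if st != "dorsal"]
    else:
        seq = list(limbs)
    n = len(seq)
    if n < 4:
        return float("nan")
    patterns = set(NORMAL_PATTERNS.values())
    matches = 0
    i = 0
    while i + 4 <= n:
        if tuple(seq[i : i + 4]) in patterns:
            matches += 1
            i += 4
        else:
            i += 1
    return 100.0 * (matches * 4) / n


def central_pattern_index(limbs: Sequence[str]) -> float:
    """CPI over a footfall placement sequence (dorsal steps included).

    Each window of 4 consecutive placements is one step cycle; it is
    correct when all four limbs appear once in a normal cyclic order.
    """
    seq = list(limbs)
    if len(seq) == 0:
        raise ValueError("empty footfall sequence")
    n_windows = len(seq) - 3
    if n_windows < 1:
        return float("nan")
    correct = sum(
        1 for i in range(n_windows) if tuple(seq[i : i + 4]) in _ROTATIONS
    )
    return 100.0 * correct / n_windows


def plantar_stepping_index(
    hindlimb_plantar: int, forelimb_plantar: int, cap: bool = True
) -> float:
    """PSI = 100 * hindlimb plantar steps / forelimb plantar steps.

    An uninjured animal steps 1:1, i.e. PSI 100.  Reported values are
    capped at 100 unless ``cap=False``.
    """
    if forelimb_plantar < 1:
        raise ValueError("PSI undefined with zero forelimb plantar steps")
    psi = 100.0 * hindlimb_plantar / forelimb_plantar
    return min(psi, 100.0) if cap else psi


def dorsal_stepping_index(
    hindlimb_cycles: Sequence[StepCycle],
) -> Tuple[float, Optional[float], Optional[float]]:
    """(DSI %, right dorsal fraction, left dorsal fraction).

    DSI is dorsal hindlimb steps over total hindlimb steps, both sides
    pooled; sidedness fractions are per-side dorsal counts over total
    dorsal counts (unset when there are no dorsal steps).
    """
    if len(hindlimb_cycles) == 0:
        raise ValueError("DSI needs at least one hindlimb cycle")
    total = len(hindlimb_cycles)
    dorsal = [c for c in hindlimb_cycles if c.step_type == "dorsal"]
    dsi = 100.0 * len(dorsal) / total
    if not dorsal:
        return dsi, None, None
    right = sum(1 for c in dorsal if c.limb == "RH") / len(dorsal)
    return dsi, right, 1.0 - right


@dataclass
class GaitIndexReport:
    """Per-pass index values with the counts behind them."""

    ri: float
    cpi: float
    psi: float
    dsi: float
    right_dorsal_fraction: Optional[float]
    left_dorsal_fraction: Optional[float]
    n_placements: int
    n_hindlimb_steps: int
    n_forelimb_plantar: int


def pass_indices(
    sequence: pd.DataFrame,
    hindlimb_cycles: Sequence[StepCycle],
) -> GaitIndexReport:
    """All four indices for one pass.

    *sequence* is a footfall sequence (columns ``time_s, limb,
    step_type``); hindlimb cycles supply the DSI denominator and dorsal
    sidedness.
    """
    limbs = sequence["limb"].tolist()
    types = sequence["step_type"].tolist()
    ri = regularity_index(limbs, types)
    cpi = central_pattern_index(limbs)
    hind_plantar = sum(
        1 for l, t in zip(limbs, types) if l in HINDLIMBS and t == "plantar"
    )
    fore_plantar = sum(
        1 for l, t in zip(limbs, types) if l not in HINDLIMBS and t == "plantar"
    )
    psi = (
        plantar_stepping_index(hind_plantar, fore_plantar)
        if fore_plantar >= 1
        else float("nan")
    )
    if hindlimb_cycles:
        dsi, rfrac, lfrac = dorsal_stepping_index(hindlimb_cycles)
    else:
        dsi, rfrac, lfrac = float("nan"), None, None
    return GaitIndexReport(
        ri=ri,
        cpi=cpi,
        psi=psi,
        dsi=dsi,
        right_dorsal_fraction=rfrac,
        left_dorsal_fraction=lfrac,
        n_placements=len(limbs),
        n_hindlimb_steps=len(hindlimb_cycles),
        n_forelimb_plantar=fore_plantar,
    )
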