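"""Hindlimb joint-angle kinematics from sagittal marker trajectories.

Four markers are digitized per hindlimb: iliac crest, hip, ankle, toe.
The knee is deliberately not marked (skin slippage over the joint makes
it unreliable), so the limb is described by two angles:

* **proximal angle** — interior angle at the hip between the segments
  hip->crest and hip->ankle;
* **distal angle** — interior angle at the ankle between the segments
  ankle->hip and ankle->toe.

Both are reported in degrees on (0, 180].  Interior angles are invariant
to rotation, translation, and uniform scaling of the marker set, which
the tests exploit as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .types import JointAngleSeries, MarkerTrackSet, StepCycle

__all__ = [
    "compute_joint_angles",
    "angle_excursion",
    "intralimb_lag",
    "stick_figure",
    "UNDEFINED_LAG",
]

#: sentinel for a cycle in which no peak pair could be identified
UNDEFINED_LAG = float("nan")

# Peak detection defaults: centered moving average over 5 frames, then
# local maxima with a minimum prominence of 5 degrees.
PEAK_SMOOTH_FRAMES = 5
PEAK_MIN_PROMINENCE_DEG = 5.0


def _interior_angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Interior angle at *vertex* between rays vertex->a and vertex->b (deg).

    Frames with a zero-length segment return NaN.
    """
    u = a - vertex
    v = b - vertex
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", u, v) / (nu * nv)
    bad = (nu == 0) | (nv == 0)
    cosang = np.where(bad, np.nan, np.clip(cosang, -1.0, 1.0))
    return np.degrees(np.arccos(cosang))


def compute_joint_angles(markers: MarkerTrackSet) -> JointAngleSeries:
    """Compute per-frame proximal (hip) and distal (ankle) angles.

    Frames where adjacent markers coincide (zero-length segment) are
    flagged in ``excluded`` and carry NaN angles; a warning reports how
    many frames were dropped.
    """
    crest = markers.marker("crest")
    hip = markers.marker("hip")
    ankle = markers.marker("ankle")
    toe = markers.marker("toe")

    proximal = _interior_angle(crest, hip, ankle)
    distal = _interior_angle(hip, ankle, toe)
    excluded = ~(np.isfinite(proximal) & np.isfinite(distal))
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} frame(s) with coincident markers excluded",
            stacklevel=2,
        )
    return JointAngleSeries(
        limb=markers.limb,
        time_s=markers.time_s,
        proximal_deg=proximal,
        distal_deg=distal,
        excluded=excluded,
    )


def angle_excursion(
    series: JointAngleSeries, window: Tuple[float, float]
) -> Tuple[float, float]:
    """(proximal, distal) max - min angle within a time window, degrees.

    Excursions are computed on the unwrapped series; flagged frames are
    ignored.  Raises if the window contains fewer than 2 valid frames.
    """
    t0, t1 = window
    mask = (series.time_s >= t0) & (series.time_s <= t1) & ~series.excluded
    if mask.sum() < 2:
        raise ValueError("excursion window must contain at least 2 frames")
    out = []
    for ang in (series.proximal_deg, series.distal_deg):
        vals = np.unwrap(np.radians(ang[mask]))
        out.append(float(np.degrees(vals.max() - vals.min())))
    return out[0], out[1]


def _smooth(x: np.ndarray, width: int = PEAK_SMOOTH_FRAMES) -> np.ndarray:
    if width <= 1 or x.size < width:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    return np.convolve(padded, kernel, mode="valid")[: x.size]


def _peaks_in(
    series_t: np.ndarray, values: np.ndarray, t0: float, t1: float
) -> np.ndarray:
    """Times of prominent local maxima of *values* within [t0, t1]."""
    sm = _smooth(values)
    idx, _ = find_peaks(sm, prominence=PEAK_MIN_PROMINENCE_DEG)
    times = series_t[idx]
    return times[(times >= t0) & (times <= t1)]


def intralimb_lag(series: JointAngleSeries, cycle: StepCycle) -> float:
    """Distal-behind-proximal peak lag as a fraction of the lead angle's cycle.

    The lead angle is the earlier-peaking of the two within the step
    cycle (proximal wins exact ties).  The lag is the distal-minus-
    proximal peak time wrapped into one lead-angle period P and divided
    by P.  Returns :data:`UNDEFINED_LAG` (NaN) when either angle shows no
    identifiable peak, so such cycles drop out of aggregates.
    """
    t0, t1 = cycle.contact_s, cycle.next_contact_s
    # search slightly beyond the cycle for the lead angle's next peak
    horizon = t1 + (t1 - t0)
    prox_pk = _peaks_in(series.time_s, series.proximal_deg, t0, horizon)
    dist_pk = _peaks_in(series.time_s, series.distal_deg, t0, horizon)
    prox_in = prox_pk[prox_pk < t1]
    dist_in = dist_pk[dist_pk < t1]
    if prox_in.size == 0 or dist_in.size == 0:
        return UNDEFINED_LAG

    if prox_in[0] <= dist_in[0]:
        lead_all, lead_first, follow_first = prox_pk, prox_in[0], dist_in[0]
    else:
        lead_all, lead_first, follow_first = dist_pk, dist_in[0], prox_in[0]
    later = lead_all[lead_all > lead_first + 1e-9]
    if later.size == 0:
        return UNDEFINED_LAG
    period = later[0] - lead_first

    delta = dist_in[0] - prox_in[0]  # signed distal - proximal peak time
    lag = np.mod(delta, period) / period
    return float(lag)


def stick_figure(
    markers: MarkerTrackSet,
    stride: Tuple[float, float],
    decimation: int = 1,
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Stick-figure polylines (crest-hip-ankle-toe) plus the toe-height trace.

    One (4, 2) polyline per retained frame, frames decimated by step
    ``decimation``; the toe-height trace covers every frame in the window
    regardless of decimation.
    """
    if decimation < 1:
        raise ValueError("decimation must be >= 1")
    t0, t1 = stride
    mask = (markers.time_s >= t0) & (markers.time_s <= t1)
    idx = np.flatnonzero(mask)
    polylines = [
        np.column_stack([markers.x[i], markers.y[i]]) for i in idx[::decimation]
    ]
    toe_height = markers.y[idx, 3]
    return polylines, toe_height
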