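"""Seeded synthetic quadruped gait generator.

Emulates the statistical structure of overground stepping and swimming
data across four behavioral conditions (uninjured / spinal-contused, each
with and without conditional silencing of long ascending propriospinal
neurons).  The generator produces the same observables the analysis
pipeline consumes: footfall event tables for all four limbs, sagittal
marker trajectories for both hindlimbs, and swim peak-extension events.

Statistical structure emulated
------------------------------
* Left-right hindlimb (and forelimb) phase concentrated at 0.5
  (alternation), with condition-dependent dispersion and a
  silencing/injury-induced mixture component centred on synchrony (0).
  Phase noise is wrapped-normal so the linear-scale 2-SD thresholds used
  downstream have an exact generative counterpart.
* Heterolateral hindlimb-forelimb contacts near-synchronous, with the
  forelimb leading by a small fraction of the cycle so that footfall
  order follows a normal step-sequence pattern.
* Per-hindlimb-step dorsal placement with condition-dependent
  probability (an SCI hallmark); dorsal steps alter only the step label,
  never the timing.
* Stance time decaying exponentially with speed, ``stance = y0 +
  a*exp(-b*speed)``; swing time approximately speed-independent.
* Intralimb proximal-distal angle coupling: sinusoidal joint-angle
  templates with configured excursions and a configurable distal lag,
  converted to marker coordinates with fixed segment lengths so the
  kinematics module can invert them exactly.

All randomness derives from one integer seed through
``numpy.random.SeedSequence`` spawning, so identical configurations give
bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import FORELIMBS, HINDLIMBS, MARKERS, MarkerTrackSet

__all__ = [
    "ConditionParams",
    "SyntheticConfig",
    "Cohort",
    "default_conditions",
    "sample_phase",
    "generate_pass",
    "generate_swim_pass",
    "generate_cohort",
]

# Fixed segment lengths (cm) for angle -> coordinate synthesis.  Arbitrary
# but recorded in the cohort manifest; the kinematics module recovers the
# generating angles from these coordinates exactly.
SEGMENT_CREST_HIP_CM = 2.5
SEGMENT_HIP_ANKLE_CM = 4.0
SEGMENT_ANKLE_TOE_CM = 2.0
HIP_HEIGHT_CM = 6.0
CREST_DIRECTION_DEG = 55.0  # fixed crest bearing from the hip (up-forward)

# Resting means around which the joint angles oscillate (degrees).  Chosen
# so that mean +/- excursion/2 stays inside (0, 180) for every condition.
PROXIMAL_MEAN_DEG = 100.0
DISTAL_MEAN_DEG = 90.0


@dataclass
class ConditionParams:
    """Generative parameters of one behavioral condition.

    ``phase_*`` and ``sync_mixture_weight`` control the left-right phase
    distribution: with probability ``1 - sync_mixture_weight`` a step's
    phase is a wrapped-normal draw around ``phase_mean`` (alternation),
    otherwise around 0 (synchrony).  ``stance_curve`` holds ``(y0, a, b)``
    of ``stance_time = y0 + a * exp(-b * speed)`` with speed in cm/s.
    """

    label: str
    phase_mean: float = 0.5
    phase_sd: float = 0.04
    sync_mixture_weight: float = 0.0
    dorsal_prob: float = 0.0
    stance_curve: Tuple[float, float, float] = (0.09, 0.30, 0.035)
    swing_mean: float = 0.10
    swing_sd: float = 0.010
    excursion_proximal: float = 50.0
    excursion_distal: float = 85.0
    intralimb_lag: float = 0.05
    speed_range: Tuple[float, float] = (35.0, 90.0)
    #: fraction of a cycle by which each forelimb leads its heterolateral
    #: hindlimb; keeps heterolateral phase near synchrony while staggering
    #: the within-couplet footfall order as in real walking.
    forelimb_lead: float = 0.10
    #: multiplicative coefficient of variation of per-stride stance noise
    stance_noise_cv: float = 0.05
    #: per-stride relative jitter of speed around the pass speed
    speed_jitter_cv: float = 0.05
    #: swim stroke period (s) and its SD
    stroke_period_s: float = 0.40
    stroke_period_sd: float = 0.04

    def __post_init__(self) -> None:
        for name in ("sync_mixture_weight", "dorsal_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.phase_mean < 1.0:
            raise ValueError("phase_mean must lie in [0, 1)")
        if self.phase_sd <= 0:
            raise ValueError("phase_sd must be positive")
        lo, hi = self.speed_range
        if not lo < hi:
            raise ValueError("speed_range min must be < max")
        y0, a, b = self.stance_curve
        for s in (lo, hi):
            if y0 + a * math.exp(-b * s) <= 0:
                raise ValueError("stance_curve yields non-positive time in speed_range")
        if self.swing_mean <= 0:
            raise ValueError("swing_mean must be positive")
        if not 0.0 <= self.intralimb_lag < 1.0:
            raise ValueError("intralimb_lag must lie in [0, 1)")

    def stance_at(self, speed: float) -> float:
        y0, a, b = self.stance_curve
        return y0 + a * math.exp(-b * speed)


def default_conditions() -> Dict[str, ConditionParams]:
    """The four study conditions with their default generative parameters.

    Dispersions and mixture weights are sized so the analytic beyond-2SD
    tail mass of the linear-phase distribution matches the irregular-step
    rates characteristic of each condition (~4% uninjured control, ~45%
    uninjured silenced, ~32% injured control, ~12% injured silenced);
    dorsal probabilities match the dorsal-stepping indices (~24% control
    vs ~12% silenced after injury); injured stance/swing/speed parameters
    are sized to the post-injury group averages (swing ~0.09-0.11 s,
    stance ~0.20-0.21 s, duty cycle ~0.67, speed ~55 cm/s).
    """
    return {
        "uninjured_control": ConditionParams(
            label="uninjured_control",
            phase_sd=0.04,
            sync_mixture_weight=0.0,
            dorsal_prob=0.0,
        ),
        "uninjured_silenced": ConditionParams(
            label="uninjured_silenced",
            phase_sd=0.05,
            sync_mixture_weight=0.38,
            dorsal_prob=0.0,
            excursion_distal=90.0,
        ),
        "sci_control": ConditionParams(
            label="sci_control",
            phase_sd=0.055,
            sync_mixture_weight=0.20,
            dorsal_prob=0.25,
            stance_curve=(0.12, 0.45, 0.040),
            swing_mean=0.090,
            swing_sd=0.012,
            excursion_proximal=47.0,
            excursion_distal=75.0,
            intralimb_lag=0.20,
            speed_range=(35.0, 75.0),
        ),
        "sci_silenced": ConditionParams(
            label="sci_silenced",
            phase_sd=0.045,
            sync_mixture_weight=0.05,
            dorsal_prob=0.12,
            stance_curve=(0.13, 0.45, 0.040),
            swing_mean=0.105,
            swing_sd=0.010,
            excursion_proximal=51.0,
            excursion_distal=85.0,
            intralimb_lag=0.10,
            speed_range=(35.0, 75.0),
        ),
    }


@dataclass
class SyntheticConfig:
    """Design of a synthetic cohort."""

    conditions: Sequence[ConditionParams]
    n_animals: int = 10
    passes_per_animal: int = 6
    strides_per_pass: Tuple[int, int] = (3, 9)
    frame_rate: float = 120.0
    seed: int = 0
    #: relative scale of mean-zero per-animal parameter jitter (0 disables)
    animal_jitter: float = 0.05
    #: generate marker trajectories (the slow part); event tables always
    include_markers: bool = True
    swim_strokes_per_pass: Tuple[int, int] = (3, 6)

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.passes_per_animal < 1:
            raise ValueError("counts must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        lo, hi = self.strides_per_pass
        if lo < 2 or hi < lo:
            raise ValueError("strides_per_pass must satisfy 2 <= min <= max")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate condition labels")


def sample_phase(params: ConditionParams, rng: np.random.Generator) -> float:
    """Draw one left-right phase value from the condition's mixture.

    With probability ``1 - sync_mixture_weight`` a wrapped-normal draw
    around ``phase_mean``; otherwise around 0 (synchrony).  Result wrapped
    to [0, 1).
    """
    mean = 0.0 if rng.random() < params.sync_mixture_weight else params.phase_mean
    return float(np.mod(rng.normal(mean, params.phase_sd), 1.0))


def _sample_phases(params: ConditionParams, n: int, rng: np.random.Generator) -> np.ndarray:
    means = np.where(
        rng.random(n) < params.sync_mixture_weight, 0.0, params.phase_mean
    )
    return np.mod(rng.normal(means, params.phase_sd), 1.0)


def generate_pass(
    params: ConditionParams,
    frame_rate: float,
    n_strides: int,
    rng: np.random.Generator,
    include_markers: bool = True,
) -> Tuple[Dict[str, MarkerTrackSet], pd.DataFrame]:
    """Generate one overground pass: hindlimb marker tracks + footfall events.

    Returns ``(markers, footfalls)`` where ``markers`` maps "LH"/"RH" to
    :class:`MarkerTrackSet` (empty dict when ``include_markers`` is False)
    and ``footfalls`` has columns ``limb, contact_s, liftoff_s, toe_x_cm,
    step_type`` for all four limbs.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if n_strides < 2:
        raise ValueError("a pass needs at least 2 strides")

    pass_speed = rng.uniform(*params.speed_range)
    stride_speeds = pass_speed * np.clip(
        1.0 + params.speed_jitter_cv * rng.normal(size=n_strides + 1), 0.5, 1.5
    )
    y0, a, b = params.stance_curve

    def stance_for(speeds: np.ndarray) -> np.ndarray:
        base = y0 + a * np.exp(-b * speeds)
        noisy = base * np.clip(
            1.0 + params.stance_noise_cv * rng.normal(size=speeds.shape), 0.3, 2.0
        )
        return np.maximum(noisy, 0.02)

    swing = np.maximum(
        rng.normal(params.swing_mean, params.swing_sd, size=n_strides + 1), 0.02
    )
    lh_stance = stance_for(stride_speeds)
    stride = lh_stance + swing  # one stride per LH cycle (last one padding)

    # LH contacts; shifted so the leading forelimb contact stays >= 0.
    t0 = params.forelimb_lead * stride[0]
    lh_contacts = t0 + np.concatenate([[0.0], np.cumsum(stride[:-1])])

    # Common body displacement: piecewise-constant speed over LH cycles.
    knot_t = np.concatenate([lh_contacts, [lh_contacts[-1] + stride[-1]]])
    knot_x = np.concatenate([[0.0], np.cumsum(stride_speeds * stride)])

    def body_x(t: np.ndarray) -> np.ndarray:
        return np.interp(t, knot_t, knot_x)

    # Hindlimb-pair and forelimb-pair phases, one per cycle.
    phase_hind = _sample_phases(params, n_strides + 1, rng)
    phase_fore = _sample_phases(params, n_strides + 1, rng)

    rh_contacts = lh_contacts + phase_hind * stride
    rf_contacts = lh_contacts - params.forelimb_lead * stride
    lf_contacts = lh_contacts + (phase_fore - params.forelimb_lead) * stride

    rows = []
    dorsal_draw = {
        "LH": rng.random(n_strides + 1) < params.dorsal_prob,
        "RH": rng.random(n_strides + 1) < params.dorsal_prob,
    }
    limb_contacts = {"LH": lh_contacts, "RH": rh_contacts, "LF": lf_contacts, "RF": rf_contacts}
    for limb, contacts in limb_contacts.items():
        contacts = np.sort(contacts)[: n_strides + 1]
        speeds_here = np.interp(contacts, knot_t, np.concatenate([stride_speeds, stride_speeds[-1:]]))
        stance_here = stance_for(speeds_here) if limb != "LH" else lh_stance
        # keep stance strictly inside the limb's own cycle
        gaps = np.diff(contacts)
        stance_here = stance_here.copy()
        stance_here[:-1] = np.minimum(stance_here[:-1], 0.85 * gaps)
        stance_here = np.maximum(stance_here, 0.02)
        toe_x = body_x(contacts) + (6.0 if limb in FORELIMBS else 0.0)
        dorsal = dorsal_draw.get(limb, np.zeros(contacts.shape, bool))
        for i in range(n_strides):  # drop the padding cycle
            rows.append(
                {
                    "limb": limb,
                    "contact_s": contacts[i],
                    "liftoff_s": contacts[i] + stance_here[i],
                    "toe_x_cm": toe_x[i],
                    "step_type": "dorsal" if dorsal[i] else "plantar",
                }
            )
    footfalls = (
        pd.DataFrame(rows)
        .sort_values(["limb", "contact_s"], kind="mergesort")
        .reset_index(drop=True)
    )

    markers: Dict[str, MarkerTrackSet] = {}
    if include_markers:
        for limb in HINDLIMBS:
            contacts = np.sort(limb_contacts[limb])[: n_strides + 1]
            markers[limb] = _synthesize_markers(
                limb, contacts, body_x, params, frame_rate
            )
    return markers, footfalls


def _synthesize_markers(
    limb: str,
    contacts: np.ndarray,
    body_x,
    params: ConditionParams,
    frame_rate: float,
) -> MarkerTrackSet:
    """Convert sinusoid-template joint angles to marker coordinates.

    The limb's cycle phase theta(t) rises linearly from 0 to 1 between its
    consecutive contacts; proximal angle peaks at theta = 0 and the distal
    angle lags it by ``intralimb_lag`` of a cycle.
    """
    t = np.arange(
        math.ceil(contacts[0] * frame_rate), math.floor(contacts[-1] * frame_rate) + 1
    ) / frame_rate
    cyc = np.interp(t, contacts, np.arange(len(contacts), dtype=float))
    theta = cyc  # fractional part carries the within-cycle phase

    prox = PROXIMAL_MEAN_DEG + 0.5 * params.excursion_proximal * np.cos(
        2 * np.pi * theta
    )
    dist = DISTAL_MEAN_DEG + 0.5 * params.excursion_distal * np.cos(
        2 * np.pi * (theta - params.intralimb_lag)
    )

    hip = np.column_stack([body_x(t), np.full(t.shape, HIP_HEIGHT_CM)])
    crest_dir = math.radians(CREST_DIRECTION_DEG)
    crest = hip + SEGMENT_CREST_HIP_CM * np.array(
        [math.cos(crest_dir), math.sin(crest_dir)]
    )
    ankle_ang = np.radians(CREST_DIRECTION_DEG - prox)
    ankle = hip + SEGMENT_HIP_ANKLE_CM * np.column_stack(
        [np.cos(ankle_ang), np.sin(ankle_ang)]
    )
    back = np.arctan2(hip[:, 1] - ankle[:, 1], hip[:, 0] - ankle[:, 0])
    toe_ang = back + np.radians(dist)
    toe = ankle + SEGMENT_ANKLE_TOE_CM * np.column_stack(
        [np.cos(toe_ang), np.sin(toe_ang)]
    )

    x = np.column_stack([crest[:, 0], hip[:, 0], ankle[:, 0], toe[:, 0]])
    y = np.column_stack([crest[:, 1], hip[:, 1], ankle[:, 1], toe[:, 1]])
    return MarkerTrackSet(limb=limb, time_s=t, x=x, y=y)


def generate_swim_pass(
    params: ConditionParams, n_strokes: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate one swim pass of hindlimb peak-extension events.

    The reference (right) hindlimb strokes at the condition's stroke
    period; the nearside (left) hindlimb's peak extension falls at a
    mixture-sampled phase of each reference stroke cycle.  Columns:
    ``limb, peak_s``.
    """
    if n_strokes < 2:
        raise ValueError("a swim pass needs at least 2 strokes")
    periods = np.maximum(
        rng.normal(params.stroke_period_s, params.stroke_period_sd, n_strokes + 1),
        0.1,
    )
    rh_peaks = np.concatenate([[0.0], np.cumsum(periods[:-1])])
    phases = _sample_phases(params, n_strokes + 1, rng)
    lh_peaks = rh_peaks + phases * periods
    rows = [{"limb": "RH", "peak_s": t} for t in rh_peaks[: n_strokes + 1]]
    rows += [{"limb": "LH", "peak_s": t} for t in lh_peaks[:n_strokes]]
    return (
        pd.DataFrame(rows)
        .sort_values(["limb", "peak_s"], kind="mergesort")
        .reset_index(drop=True)
    )


@dataclass
class Cohort:
    """A generated dataset keyed by (condition, animal, pass)."""

    config: SyntheticConfig
    #: (condition, animal_id, pass_id) -> {"LH": MarkerTrackSet, "RH": ...}
    markers: Dict[Tuple[str, int, int], Dict[str, MarkerTrackSet]]
    #: footfall events, columns: condition, animal, pass, limb, contact_s,
    #: liftoff_s, toe_x_cm, step_type
    footfalls: pd.DataFrame
    #: swim events, columns: condition, animal, pass, limb, peak_s
    swim: pd.DataFrame
    #: realized per-animal parameters and fixed synthesis constants
    manifest: dict


def _jitter_params(
    params: ConditionParams, scale: float, rng: np.random.Generator
) -> ConditionParams:
    """Mean-zero per-animal jitter of the main generative parameters."""
    if scale <= 0:
        return params
    y0, a, b = params.stance_curve
    j = lambda: 1.0 + scale * rng.normal()  # noqa: E731
    return ConditionParams(
        label=params.label,
        phase_mean=float(np.clip(params.phase_mean + 0.1 * scale * rng.normal(), 0.0, 0.999)),
        phase_sd=params.phase_sd * max(j(), 0.2),
        sync_mixture_weight=float(np.clip(params.sync_mixture_weight * j(), 0.0, 1.0)),
        dorsal_prob=float(np.clip(params.dorsal_prob * j(), 0.0, 1.0)),
        stance_curve=(y0 * max(j(), 0.2), a * max(j(), 0.2), b * max(j(), 0.2)),
        swing_mean=params.swing_mean * max(j(), 0.2),
        swing_sd=params.swing_sd,
        excursion_proximal=params.excursion_proximal * max(j(), 0.2),
        excursion_distal=params.excursion_distal * max(j(), 0.2),
        intralimb_lag=params.intralimb_lag,
        speed_range=params.speed_range,
        forelimb_lead=params.forelimb_lead,
        stance_noise_cv=params.stance_noise_cv,
        speed_jitter_cv=params.speed_jitter_cv,
        stroke_period_s=params.stroke_period_s,
        stroke_period_sd=params.stroke_period_sd,
    )


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full multi-condition cohort from one integer seed."""
    root = np.random.SeedSequence(config.seed)
    markers: Dict[Tuple[str, int, int], Dict[str, MarkerTrackSet]] = {}
    footfall_frames: List[pd.DataFrame] = []
    swim_frames: List[pd.DataFrame] = []
    manifest: dict = {
        "seed": config.seed,
        "frame_rate": config.frame_rate,
        "segment_lengths_cm": {
            "crest_hip": SEGMENT_CREST_HIP_CM,
            "hip_ankle": SEGMENT_HIP_ANKLE_CM,
            "ankle_toe": SEGMENT_ANKLE_TOE_CM,
        },
        "animals": [],
    }

    cond_seeds = root.spawn(len(config.conditions))
    for params, cond_seed in zip(config.conditions, cond_seeds):
        animal_seeds = cond_seed.spawn(config.n_animals)
        for animal in range(config.n_animals):
            arng = np.random.default_rng(animal_seeds[animal])
            realized = _jitter_params(params, config.animal_jitter, arng)
            entry = asdict(realized)
            entry.update({"condition": params.label, "animal": animal})
            manifest["animals"].append(entry)
            for pass_id in range(config.passes_per_animal):
                n_strides = int(
                    arng.integers(config.strides_per_pass[0], config.strides_per_pass[1] + 1)
                )
                mk, ff = generate_pass(
                    realized,
                    config.frame_rate,
                    n_strides,
                    arng,
                    include_markers=config.include_markers,
                )
                ff.insert(0, "condition", params.label)
                ff.insert(1, "animal", animal)
                ff.insert(2, "pass", pass_id)
                footfall_frames.append(ff)
                if mk:
                    markers[(params.label, animal, pass_id)] = mk
                n_strokes = int(
                    arng.integers(
                        config.swim_strokes_per_pass[0],
                        config.swim_strokes_per_pass[1] + 1,
                    )
                )
                sw = generate_swim_pass(realized, n_strokes, arng)
                sw.insert(0, "condition", params.label)
                sw.insert(1, "animal", animal)
                sw.insert(2, "pass", pass_id)
                swim_frames.append(sw)

    footfalls = pd.concat(footfall_frames, ignore_index=True)
    swim = pd.concat(swim_frames, ignore_index=True)
    return Cohort(
        config=config, markers=markers, footfalls=footfalls, swim=swim, manifest=manifest
    )
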