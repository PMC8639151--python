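# Methods

This note documents the models, conventions, parameters, and design
choices behind quadgait: what the analysis computes, what the synthetic
generator emulates (and what it does not), and the numerical decisions
that matter for reproducing its outputs.

## Units and conventions

Times in seconds, positions in centimeters, angles in degrees. Sagittal
plane: x is the direction of travel, y vertical. Frame indices are
0-based; a stride is the half-open interval [contact, next contact) of
one limb. Simultaneous paw placements are ordered LH < RH < LF < RF so
pattern matching is deterministic.

## Step cycles and spatiotemporal measures

A per-frame contact trace is debounced by merging contact-state runs
shorter than 3 frames into their surroundings (digitization noise);
each contact-onset → next-onset interval containing a lift-off becomes
a cycle with stance = onset → offset, swing = offset → next onset,
stride distance = |toe x at next onset − toe x at onset|, and
instantaneous speed = stride distance / stride time. Event tables skip
debouncing; rows whose lift-off does not fall strictly inside the
contact interval (overlapping double contacts) are dropped. Pass speed
is stride-derived (mean of per-step instantaneous speeds), not taken
from a separate body marker.

## Interlimb phase and irregularity

Reference limbs: left hindlimb for the hindlimb pair and for both
hindlimb–forelimb pairs, left forelimb for the forelimb pair, right
hindlimb for the swim pair. Cycles containing no test-limb contact
contribute no observation; cycles with several contribute one
observation per contact, flagged as multi-step (these are exactly the
double steps CPI detects, so they are kept, not dropped).

The circular→linear transform reflects raw phase about 0.5:
linear = raw if raw ≥ 0.5 else 1 − raw for alternating pairs, and the
mirror image (onto [0, 0.5]) for the heterolateral pair. It satisfies
T(raw) = T(1 − raw) (lead-limb symmetry) and is idempotent on its
output range.

Irregularity thresholds are the control mean ± 2 sample SD (n − 1
denominator) computed **on the linear scale** — the classification
boxes are drawn on linear axes, so a linear SD is the faithful spread
measure even though the underlying variable is circular. Control values
are pooled across animals of the control condition (per-animal
thresholds are possible via the library but not the default). A value
exactly on a bound is regular; only values strictly beyond 2 SD count.
Post-injury steps are classified against thresholds derived from the
*uninjured* control distribution.

## Gait indices

The six normal step-sequence patterns (cruciate, alternate, rotary;
two lead variants each):

| label | order |
|---|---|
| Ca | RF → LF → RH → LH |
| Cb | LF → RF → LH → RH |
| Aa | RF → LH → LF → RH |
| Ab | LF → RH → RF → LH |
| Ra | RF → LF → LH → RH |
| Rb | LF → RF → RH → LH |

RI removes dorsal placements, then scans the remaining placement string
left-to-right, greedily and non-overlappingly, for these six literal
sequences; the denominator counts post-exclusion placements (consistent
with "RI excludes dorsal steps"; the alternative pre-exclusion
denominator is not used).

CPI advances a four-placement window one placement at a time; a window
is correctly patterned when it contains each limb exactly once in a
normal *cyclic* order, i.e., it is some rotation of one of the six
patterns. Rotation invariance is deliberate: a rolling window samples a
periodic footfall sequence at every offset, so anchored (literal)
matching would score a perfectly patterned pass at 25%, not 100%. The
six patterns cover five of the six cyclic orders of four limbs; the
sixth — the hindlimb-leading diagonal order LH, RF, RH, LF — is the one
abnormal class. A limb repeated within a window (girdle-level
irregularity, double steps) breaks both an RI match and CPI
correctness.

Indices are computed per pass, averaged per animal, and group averages
are means of animal means.

## Kinematics

With no knee marker, the limb is a two-angle model: proximal (hip)
angle between hip→crest and hip→ankle, distal (ankle) angle between
ankle→hip and ankle→toe, both interior angles in (0, 180] and invariant
to rotation, translation, and uniform scaling. Frames with coincident
adjacent markers are flagged and excluded with a warning. Excursions
are max − min of the unwrapped series in a window. Peak detection for
the intralimb lag uses a centered 5-frame moving average and a 5°
minimum prominence (both configurable constants); the lag is the
distal-minus-proximal peak time wrapped into one period of the lead
(earlier-peaking; proximal on exact ties) angle and divided by that
period. Cycles without an identifiable peak pair return NaN and drop
out of aggregates.

## Statistics

- **Two-proportion z**: z = (p̂₂ − p̂₁)/SE, two-tailed normal p. Both
  variance conventions are implemented because the published legend
  values are internally consistent only if the overground comparisons
  used the unpooled SE and the swimming comparisons the pooled SE
  (verified arithmetically from the printed counts); the default is
  unpooled and the variant is recorded in every result.
- **Watson two-sample U²** from the pooled-ranked ECDFs on the circle,
  tie-aware; invariant to a common rotation of both samples. The
  p-value is by seeded label permutation (default 9,999 permutations;
  p = (1 + #{U* ≥ U})/(B + 1)); an asymptotic tail series
  2·Σ(−1)^(m−1)·exp(−2m²π²U²) is available for large samples.
- **Circular descriptives**: values ×2π, vector-averaged; R is the
  resultant length and circular SD = √(−2 ln R). R = 0 leaves the mean
  undefined (NaN sentinel).
- **Speed curves**: stance/stride time follow y = y0 + a·e^(−bx)
  (the "exponential decay" form, fixed since no equation is printed in
  the sources this emulates), stride distance is linear. 95% prediction
  intervals use residual variance plus local fit variance (delta method
  for the exponential) with a t quantile at n − p dof; empirical
  coverage is verified at 95% ± 2% by simulation.
- **Paired t** on differences, df = n − 1; zero-variance nonzero
  differences raise, identical samples give t = 0.
- No multiple-testing correction is applied by default (per-comparison
  p-values are reported).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not limb mechanics: there is no musculoskeletal or CPG dynamics, no
video, and no 3D camera model.

- **Phase**: left–right phase is a two-component wrapped-normal
  mixture — alternation (mean 0.5) with probability 1 − w, synchrony
  (mean 0) with probability w. Wrapped-normal (not von Mises) noise is
  used so the linear-scale 2-SD thresholds downstream have an exact
  generative counterpart. Forelimb-pair phase is sampled independently
  of the hindlimb pair but shares stride timing.
- **Timing**: per-stride stance = y0 + a·e^(−b·speed) with 5%
  multiplicative noise; swing ~ N(swing_mean, swing_sd); stride =
  stance + swing. Each forelimb leads its heterolateral hindlimb by
  0.10 of a cycle — near-synchronous on the heterolateral scale while
  staggering the diagonal couplet as real walking does (exactly
  simultaneous couplets would make footfall order a coin flip and no
  placement sequence could be "normal").
- **Dorsal steps** flip only the step label (probability dorsal_prob
  per hindlimb step), never timing — dorsal steps act as category
  labels downstream.
- **Markers**: sinusoidal joint-angle templates (proximal peaks at
  cycle phase 0, distal lags by intralimb_lag) are converted to
  coordinates with fixed segment lengths (crest–hip 2.5, hip–ankle 4,
  ankle–toe 2 cm, recorded in the manifest) chosen so the kinematics
  module inverts them exactly and angle means ± excursion/2 stay inside
  (0, 180).
- **Seeding**: one integer seed feeds a `SeedSequence` tree (condition
  → animal → pass); identical configurations give bit-identical
  tables. Per-animal parameter jitter is mean-zero and small (5%
  relative by default, 0 disables).
- **Swimming**: the reference hindlimb strokes at ~0.4 s periods; the
  nearside peak-extension time falls at a mixture-sampled phase of each
  stroke cycle.

### Condition parameters and how they were chosen

The four conditions encode the contrasts the analysis must resolve.
Phase dispersion and mixture weight per condition were derived
analytically from the characteristic irregular-step rates (fraction
beyond a 2σ_control ≈ 0.08 threshold is ≈ w + (1 − w)·2Φ(−0.08/σ)):

| condition | σ (cycle) | w | dorsal_prob | target irregular |
|---|---|---|---|---|
| uninjured control | 0.040 | 0 | 0 | ~4% |
| uninjured silenced | 0.050 | 0.38 | 0 | ~45% |
| SCI control | 0.055 | 0.20 | 0.25 | ~32% |
| SCI silenced | 0.045 | 0.05 | 0.12 | ~12% |

Dorsal probabilities mirror the dorsal-stepping indices (~24% vs ~12%);
the injured conditions' stance/swing/speed parameters are sized to
post-injury group averages (swing ≈ 0.09–0.11 s, stance ≈ 0.20 s, duty
cycle ≈ 0.67, speed ≈ 55 cm/s); joint-angle excursions and intralimb
lags follow the reported direction (smaller excursions and larger lag
after injury, partially restored under silencing). Camera frame rate
(120 fps) and strides per pass (3–9) are configurable defaults, not
claims about any particular dataset.

### What passing tests show — and what they do not

The generator produces idealized data: contact events are exact (no
digitization error beyond what debouncing models), joint angles are
noiseless sinusoids, phase noise is independent across strides (no
autocorrelation or drift within a pass), dorsal steps are independent
Bernoulli draws, and forelimbs never step dorsally. Tests passing on
this structure demonstrate that the pipeline's arithmetic is correct
and that it recovers known generative parameters; they do not
demonstrate robustness to marker dropout, skin slippage,
autocorrelated gait drift, or observer-dependent event labeling in
real video data.

## Problem sizes and numerical notes

Analysis drivers and the reproduction script use cohorts of 4–6
animals × 4–8 passes × 5–9 strides per condition (a few hundred steps
per condition), matching the scale at which parameter recovery is
well-posed and keeping any run in seconds. Stance-curve recovery is
assessed over a 10–100 cm/s speed span: over a narrow walking-speed
band (say 35–75 cm/s) the (a, b) pair of the exponential is weakly
identified — the estimator is consistent but its sampling error exceeds
10% for a substantial fraction of cohorts at n ≈ 300, an experimental
design limit rather than an algorithmic one. The exponential fit
starts from (min y, range y, 1/mean x) and raises on non-convergence
with diagnostics. Degenerate inputs have defined behavior throughout:
zero-spread controls, zero-variance paired differences, zero forelimb
plantar steps, and zero-length segments all raise; R = 0 circular
means, undefined lags, and sub-window footfall strings return NaN
sentinels that drop out of aggregates.

## Known limitations

Planar sagittal coordinates only (two-camera 3D reconstruction is out
of scope); dorsal steps are consumed as input labels, not inferred from
images; BBB scores are observer ratings and are not computed; mixed
and repeated-measures ANOVA are left to general statistics packages.
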