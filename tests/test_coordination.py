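"""Interlimb phase, circular->linear transform, 2-SD classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from quadgait.coordination import (
    classify_irregular,
    control_threshold,
    interlimb_phase,
    stroke_cycles,
    swim_phase,
    transform_phase,
)
from quadgait.types import StepCycle


def _ref_cycles(contacts):
    out = []
    for a, b in zip(contacts, contacts[1:]):
        out.append(
            StepCycle(
                limb="LH",
                contact_s=a,
                liftoff_s=a + 0.55 * (b - a),
                next_contact_s=b,
                stride_distance_cm=10.0,
            )
        )
    return out


class TestInterlimbPhase:
    def test_contact_at_cycle_start_is_zero(self):
        obs = interlimb_phase(_ref_cycles([0.0, 0.4]), [0.0], "hindlimb")
        assert obs[0].raw_phase == 0.0

    def test_midcycle_contact_is_half(self):
        obs = interlimb_phase(_ref_cycles([0.0, 0.4]), [0.2], "hindlimb")
        assert obs[0].raw_phase == pytest.approx(0.5)

    def test_contact_in_second_cycle(self):
        obs = interlimb_phase(_ref_cycles([0.0, 0.4, 0.8]), [0.5], "hindlimb")
        assert len(obs) == 1
        assert obs[0].reference_index == 1
        assert obs[0].raw_phase == pytest.approx(0.25)

    def test_multiple_contacts_flagged_multi_step(self):
        obs = interlimb_phase(_ref_cycles([0.0, 0.4]), [0.1, 0.3], "hindlimb")
        assert len(obs) == 2 and all(o.multi_step for o in obs)

    def test_cycle_without_test_contact_yields_nothing(self):
        obs = interlimb_phase(_ref_cycles([0.0, 0.4, 0.8]), [0.6], "hindlimb")
        assert len(obs) == 1 and obs[0].reference_index == 1


class TestTransform:
    @pytest.mark.parametrize(
        "pair,raw,expected",
        [
            ("hindlimb", 0.3, 0.7),
            ("hindlimb", 0.7, 0.7),
            ("forelimb", 0.5, 0.5),
            ("homolateral", 0.1, 0.9),
            ("heterolateral", 0.95, 0.05),
            ("heterolateral", 0.3, 0.3),
            ("swim", 0.2, 0.8),
        ],
    )
    def test_examples(self, pair, raw, expected):
        assert transform_phase(raw, pair) == pytest.approx(expected)

    @given(raw=hst.floats(0, 0.999999), pair=hst.sampled_from(["hindlimb", "heterolateral"]))
    @settings(deadline=None, max_examples=200)
    def test_lead_limb_symmetry_and_idempotence(self, raw, pair):
        a = transform_phase(raw, pair)
        b = transform_phase((1.0 - raw) % 1.0, pair)
        assert a == pytest.approx(b, abs=1e-12)
        assert transform_phase(a % 1.0, pair) == pytest.approx(a, abs=1e-12)

    def test_out_of_range_raw_errors(self):
        with pytest.raises(ValueError):
            transform_phase(1.5, "hindlimb")


class TestControlThreshold:
    def test_exact_bounds_from_constructed_sample(self):
        # mean 0.7, sample SD exactly 0.05
        vals = np.array([0.65, 0.75, 0.65, 0.75, 0.65, 0.75])
        sd = vals.std(ddof=1)
        scaled = 0.7 + (vals - 0.7) * (0.05 / sd)
        thr = control_threshold(scaled, "hindlimb")
        assert thr.control_mean == pytest.approx(0.7)
        assert thr.control_sd == pytest.approx(0.05)
        assert thr.lower == pytest.approx(0.6)
        assert thr.upper == pytest.approx(0.8)

    def test_degenerate_zero_spread_errors(self):
        with pytest.raises(ValueError):
            control_threshold([0.5] * 10, "hindlimb")

    def test_bounds_clipped_to_pair_range(self):
        rng = np.random.default_rng(0)
        vals = 0.5 + np.abs(rng.normal(0, 0.04, 100))
        thr = control_threshold(vals, "hindlimb")
        assert thr.lower >= 0.5 and thr.upper <= 1.0

    def test_independent_sample_coverage_near_95(self):
        """~95.4% of a same-distribution sample falls inside mean +/- 2 SD."""
        rng = np.random.default_rng(11)
        control = rng.normal(0.7, 0.04, 200)
        thr = control_threshold(control, "hindlimb")
        fresh = rng.normal(0.7, 0.04, 20000)
        _, k, n, _ = classify_irregular(fresh, thr)
        coverage = 1 - k / n
        assert coverage == pytest.approx(0.954, abs=0.03)


class TestClassify:
    def test_printed_percentage_arithmetic(self):
        thr = control_threshold(
            np.array([0.68, 0.72, 0.70, 0.69, 0.71]), "hindlimb"
        )
        values = np.concatenate([np.full(72, 0.99), np.full(161 - 72, thr.control_mean)])
        _, k, n, pct = classify_irregular(values, thr)
        assert (k, n, pct) == (72, 161, 44.72)

    def test_all_values_at_mean_gives_zero(self):
        thr = control_threshold(np.array([0.68, 0.72, 0.70, 0.71, 0.69]), "hindlimb")
        _, k, _, pct = classify_irregular(np.full(50, thr.control_mean), thr)
        assert k == 0 and pct == 0.0

    def test_boundary_value_is_regular(self):
        vals = np.array([0.65, 0.75, 0.65, 0.75, 0.65, 0.75])
        sd = vals.std(ddof=1)
        thr = control_threshold(0.7 + (vals - 0.7) * (0.05 / sd), "hindlimb")
        flags, k, _, _ = classify_irregular([thr.lower, thr.upper], thr)
        assert k == 0

    def test_mixture_flag_rate_matches_analytic_tail(self):
        """Flagged fraction of a synchrony mixture matches its tail mass."""
        from scipy import stats as sps

        rng = np.random.default_rng(21)
        w, sd = 0.3, 0.05
        n = 4000
        sync = rng.random(n) < w
        raw = np.where(
            sync, rng.normal(0.0, sd, n), rng.normal(0.5, sd, n)
        ) % 1.0
        linear = np.where(raw >= 0.5, raw, 1 - raw)
        control = np.mod(rng.normal(0.5, 0.04, 300), 1.0)
        lin_ctrl = np.where(control >= 0.5, control, 1 - control)
        thr = control_threshold(lin_ctrl, "hindlimb")
        _, k, nn, _ = classify_irregular(linear, thr)
        # analytic: sync component nearly always beyond; alternating
        # component beyond when |raw - 0.5| exceeds the upper bound offset
        off = thr.upper - 0.5
        p_alt = 2 * sps.norm.sf(off / sd)
        p_expected = w * 1.0 + (1 - w) * p_alt  # sync component is ~always beyond
        lo, hi = sps.binom.ppf([0.001, 0.999], nn, p_expected) / nn
        assert lo <= k / nn <= hi


class TestSwim:
    def test_peak_at_cycle_start_and_midcycle(self):
        cycles = stroke_cycles([0.0, 0.4, 0.8])
        obs = swim_phase([0.0, 0.6], cycles)
        assert obs[0].raw_phase == pytest.approx(0.0)
        assert obs[1].raw_phase == pytest.approx(0.5)
        assert obs[1].linear_phase == pytest.approx(0.5)

    def test_alternating_strokes_rarely_flagged(self, rng):
        periods = 0.4 + rng.normal(0, 0.02, 120)
        ref = np.concatenate([[0.0], np.cumsum(periods)])
        cycles = stroke_cycles(ref)
        phases = np.mod(rng.normal(0.5, 0.03, len(cycles)), 1.0)
        peaks = ref[:-1] + phases * np.diff(ref)
        obs = swim_phase(peaks, cycles)
        control = np.mod(rng.normal(0.5, 0.03, 300), 1.0)
        lin_ctrl = np.where(control >= 0.5, control, 1 - control)
        thr = control_threshold(lin_ctrl, "swim")
        _, k, n, _ = classify_irregular([o.linear_phase for o in obs], thr)
        assert k / n < 0.12
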