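"""Synthetic gait generator: determinism, event sanity, distributions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from quadgait import simulate as sim
from quadgait.pipeline import segment_pass
from quadgait.stats import circular_descriptives


class TestSamplePhase:
    def test_degenerate_dispersion_returns_mean(self):
        p = sim.ConditionParams(label="t", phase_sd=1e-12, sync_mixture_weight=0.0)
        rng = np.random.default_rng(0)
        assert sim.sample_phase(p, rng) == pytest.approx(0.5, abs=1e-9)

    def test_pure_sync_component_returns_zero(self):
        p = sim.ConditionParams(label="t", phase_sd=1e-12, sync_mixture_weight=1.0)
        rng = np.random.default_rng(0)
        from quadgait.types import circular_distance

        assert circular_distance(sim.sample_phase(p, rng), 0.0) < 1e-9

    def test_circular_mean_recovers_target(self):
        p = sim.ConditionParams(label="t", phase_sd=0.05, sync_mixture_weight=0.0)
        rng = np.random.default_rng(1)
        draws = [sim.sample_phase(p, rng) for _ in range(10000)]
        mean, _, _ = circular_descriptives(draws)
        se = 0.05 / np.sqrt(10000)
        assert abs(mean - 0.5) <= 3 * se


class TestGeneratePass:
    def test_same_seed_bit_identical(self, conditions):
        p = conditions["sci_control"]
        mk1, ff1 = sim.generate_pass(p, 120.0, 6, np.random.default_rng(9))
        mk2, ff2 = sim.generate_pass(p, 120.0, 6, np.random.default_rng(9))
        pd.testing.assert_frame_equal(ff1, ff2)
        for limb in mk1:
            np.testing.assert_array_equal(mk1[limb].x, mk2[limb].x)
            np.testing.assert_array_equal(mk1[limb].y, mk2[limb].y)

    def test_event_sanity_contact_liftoff_order(self, conditions):
        for label, p in conditions.items():
            _, ff = sim.generate_pass(
                p, 120.0, 8, np.random.default_rng(3), include_markers=False
            )
            assert (ff["contact_s"] < ff["liftoff_s"]).all(), label
            for limb, grp in ff.groupby("limb"):
                assert grp["contact_s"].is_monotonic_increasing

    def test_stance_plus_swing_equals_stride(self, conditions):
        _, ff = sim.generate_pass(
            conditions["uninjured_control"], 120.0, 8,
            np.random.default_rng(4), include_markers=False,
        )
        for limb, cycles in segment_pass(ff).items():
            for c in cycles:
                assert c.stance_s + c.swing_s == pytest.approx(c.stride_s, abs=1e-9)

    def test_dorsal_fraction_within_exact_binomial_interval(self):
        p = sim.ConditionParams(label="t", dorsal_prob=0.25)
        rng = np.random.default_rng(6)
        dorsal = total = 0
        while total < 400:
            _, ff = sim.generate_pass(p, 120.0, 8, rng, include_markers=False)
            hind = ff[ff["limb"].isin(["LH", "RH"])]
            total += len(hind)
            dorsal += (hind["step_type"] == "dorsal").sum()
        lo = sps.binom.ppf(0.025, total, 0.25)
        hi = sps.binom.ppf(0.975, total, 0.25)
        assert lo <= dorsal <= hi

    def test_phase_spread_within_two_realized_sd(self):
        p = sim.ConditionParams(label="t", phase_sd=0.03, sync_mixture_weight=0.0)
        rng = np.random.default_rng(8)
        from quadgait.pipeline import cohort_phase_table

        frames = []
        for k in range(30):
            _, ff = sim.generate_pass(p, 120.0, 8, rng, include_markers=False)
            ff.insert(0, "pass", k)
            frames.append(ff)
        ph = cohort_phase_table(pd.concat(frames, ignore_index=True), pairs=("hindlimb",))
        raw = ph["raw_phase"].to_numpy()
        mean, sd = raw.mean(), raw.std(ddof=1)
        inside = np.mean(np.abs(raw - mean) <= 2 * sd)
        assert inside >= 0.95

    def test_degenerate_frame_rate_rejected(self, conditions):
        with pytest.raises(ValueError):
            sim.generate_pass(
                conditions["uninjured_control"], 0.0, 5, np.random.default_rng(0)
            )


class TestCohort:
    def test_bookkeeping_counts_and_manifest(self, small_cohort):
        cfg = small_cohort.config
        n_passes = cfg.n_animals * cfg.passes_per_animal
        counts = small_cohort.footfalls.groupby("condition")[["pass"]].nunique()
        for cond in [c.label for c in cfg.conditions]:
            got = small_cohort.footfalls[small_cohort.footfalls["condition"] == cond]
            assert len(got.groupby(["animal", "pass"])) == n_passes
        assert len(small_cohort.manifest["animals"]) == len(cfg.conditions) * cfg.n_animals

    def test_adjacent_seeds_differ(self, conditions):
        base = dict(
            conditions=[conditions["uninjured_control"]],
            n_animals=1, passes_per_animal=1, strides_per_pass=(4, 4),
            include_markers=False,
        )
        a = sim.generate_cohort(sim.SyntheticConfig(seed=5, **base))
        b = sim.generate_cohort(sim.SyntheticConfig(seed=6, **base))
        assert not a.footfalls["contact_s"].equals(b.footfalls["contact_s"])

    def test_cohort_determinism(self, conditions):
        base = dict(
            conditions=[conditions["sci_silenced"]],
            n_animals=2, passes_per_animal=2, strides_per_pass=(4, 6),
            include_markers=False,
        )
        a = sim.generate_cohort(sim.SyntheticConfig(seed=12, **base))
        b = sim.generate_cohort(sim.SyntheticConfig(seed=12, **base))
        pd.testing.assert_frame_equal(a.footfalls, b.footfalls)
        pd.testing.assert_frame_equal(a.swim, b.swim)

    def test_duplicate_condition_labels_rejected(self, conditions):
        p = conditions["uninjured_control"]
        with pytest.raises(ValueError, match="duplicate"):
            sim.SyntheticConfig(conditions=[p, p])

    def test_dorsal_prob_contrast_propagates_to_dsi(self, conditions):
        from quadgait.pipeline import aggregate_indices, cohort_index_table

        cfg = sim.SyntheticConfig(
            conditions=[conditions["uninjured_control"], conditions["sci_control"]],
            n_animals=3, passes_per_animal=3, strides_per_pass=(5, 8),
            seed=20, include_markers=False,
        )
        cohort = sim.generate_cohort(cfg)
        g = aggregate_indices(cohort_index_table(cohort.footfalls)).set_index("condition")
        assert g.loc["sci_control", "dsi_mean"] > g.loc["uninjured_control", "dsi_mean"]


class TestValidation:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            sim.ConditionParams(label="bad", dorsal_prob=1.5)

    def test_speed_range_ordering_enforced(self):
        with pytest.raises(ValueError):
            sim.ConditionParams(label="bad", speed_range=(80.0, 40.0))

    def test_stance_curve_positivity_enforced(self):
        with pytest.raises(ValueError):
            sim.ConditionParams(label="bad", stance_curve=(-0.5, 0.1, 0.01))
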