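"""Proportion, circular, regression, and paired-t procedures."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from quadgait.stats import (
    circular_descriptives,
    fit_speed_curve,
    paired_t,
    two_proportion_z,
    watson_u2,
    watson_u2_statistic,
)


class TestTwoProportion:
    def test_equal_proportions_give_zero(self):
        assert two_proportion_z(20, 100, 40, 200).z == pytest.approx(0.0)

    @given(
        k1=hst.integers(1, 99),
        k2=hst.integers(1, 99),
        variant=hst.sampled_from(["pooled", "unpooled"]),
    )
    @settings(deadline=None, max_examples=100)
    def test_swapping_groups_negates_z(self, k1, k2, variant):
        a = two_proportion_z(k1, 100, k2, 100, variant)
        b = two_proportion_z(k2, 100, k1, 100, variant)
        assert a.z == pytest.approx(-b.z, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_degenerate_zero_se_errors(self):
        with pytest.raises(ValueError):
            two_proportion_z(0, 50, 0, 60)

    def test_pooled_and_unpooled_differ_when_rates_differ(self):
        a = two_proportion_z(7, 168, 72, 161, "unpooled")
        b = two_proportion_z(7, 168, 72, 161, "pooled")
        assert abs(a.z) != pytest.approx(abs(b.z), abs=0.1)


class TestWatsonU2:
    def test_identical_shuffled_samples_have_high_p(self, rng):
        vals = rng.random(30)
        res = watson_u2(vals, rng.permutation(vals), n_permutations=499, seed=0)
        assert res.p >= 0.9

    def test_statistic_matches_exhaustive_permutation_oracle(self):
        a = [0.02, 0.48, 0.51, 0.55, 0.97]
        b = [0.10, 0.22, 0.31, 0.60, 0.75]
        u_obs = watson_u2_statistic(np.array(a), np.array(b))

        # oracle: direct ECDF-difference computation + all C(10,5) splits
        def u2_direct(x, y):
            x, y = sorted(x), sorted(y)
            pooled = sorted(x + y)
            d = []
            for z in pooled:
                fx = sum(v <= z for v in x) / len(x)
                fy = sum(v <= z for v in y) / len(y)
                d.append(fx - fy)
            n = len(pooled)
            dbar = sum(d) / n
            return (len(x) * len(y) / n**2) * sum((di - dbar) ** 2 for di in d)

        assert u_obs == pytest.approx(u2_direct(a, b), abs=1e-12)

        pooled = a + b
        count = total = 0
        for comb in itertools.combinations(range(10), 5):
            xa = [pooled[i] for i in comb]
            xb = [pooled[i] for i in range(10) if i not in comb]
            total += 1
            if u2_direct(xa, xb) >= u_obs - 1e-12:
                count += 1
        exact_p = count / total
        res = watson_u2(a, b, n_permutations=4999, seed=3)
        assert res.p == pytest.approx(exact_p, abs=0.05)

    @given(shift=hst.floats(0, 1))
    @settings(deadline=None, max_examples=30)
    def test_common_rotation_invariance(self, shift):
        rng = np.random.default_rng(17)
        a = rng.random(12)
        b = np.mod(rng.normal(0.5, 0.1, 15), 1)
        u1 = watson_u2_statistic(a, b)
        u2 = watson_u2_statistic((a + shift) % 1.0, (b + shift) % 1.0)
        assert u2 == pytest.approx(u1, abs=1e-9)

    def test_separated_samples_detected(self):
        rng = np.random.default_rng(5)
        a = np.mod(rng.normal(0.5, 0.05, 50), 1)
        b = np.mod(rng.normal(0.0, 0.05, 50), 1)
        res = watson_u2(a, b, n_permutations=999, seed=5)
        assert res.p < 0.01

    def test_asymptotic_calibration_at_critical_value(self):
        # U^2 = 0.187 is the classical 5% critical point
        from quadgait.stats import _watson_asymptotic_p

        assert _watson_asymptotic_p(0.187) == pytest.approx(0.05, abs=0.003)


class TestCircularDescriptives:
    def test_concentrated_sample(self):
        mean, r, sd = circular_descriptives([0.5] * 8)
        assert mean == pytest.approx(0.5) and r == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_uniform_four_points_have_zero_resultant(self):
        mean, r, _ = circular_descriptives([0.0, 0.25, 0.5, 0.75])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(mean)

    def test_matches_vector_sum_oracle(self, rng):
        vals = rng.random(200)
        mean, r, sd = circular_descriptives(vals)
        z = np.exp(2j * np.pi * vals).mean()
        assert r == pytest.approx(abs(z), abs=1e-12)
        assert mean == pytest.approx((np.angle(z) / (2 * np.pi)) % 1.0, abs=1e-12)
        assert sd == pytest.approx(math.sqrt(-2 * math.log(abs(z))), abs=1e-12)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        vals = np.mod(rng.normal(0.5, 0.1, 100), 1)
        mean, r, _ = circular_descriptives(vals)
        ang = 2 * np.pi * vals
        assert mean == pytest.approx((pg.circ_mean(ang) / (2 * np.pi)) % 1.0, abs=1e-9)
        assert r == pytest.approx(pg.circ_r(ang), abs=1e-9)


class TestSpeedCurve:
    def test_noiseless_exponential_recovery(self):
        x = np.linspace(10, 100, 40)
        y = 0.05 + 0.4 * np.exp(-0.06 * x)
        fit = fit_speed_curve(x, y, "exponential_decay")
        assert fit.coefficients == pytest.approx((0.05, 0.4, 0.06), abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_linear_recovery(self):
        x = np.linspace(0, 50, 20)
        fit = fit_speed_curve(x, 2 + 0.3 * x, "linear")
        assert fit.coefficients == pytest.approx((2.0, 0.3), abs=1e-9)

    def test_prediction_interval_contains_fitted_curve(self, rng):
        x = rng.uniform(10, 100, 60)
        y = 0.05 + 0.4 * np.exp(-0.06 * x) + rng.normal(0, 0.01, 60)
        fit = fit_speed_curve(x, y, "exponential_decay")
        xg = np.linspace(10, 100, 25)
        lo, hi = fit.prediction_interval(xg)
        yhat = fit.predict(xg)
        assert np.all(lo < yhat) and np.all(yhat < hi)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            fit_speed_curve([1, 2, 3], [1, 2, 3], "exponential_decay")


class TestPairedT:
    def test_identical_samples_give_zero_t(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and df == 2 and p == 1.0

    def test_constant_nonzero_difference_errors(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_ten_pair_fixture_matches_closed_form(self):
        a = [74.62, 85.74, 75.29, 83.40, 47.64, 51.47, 46.45, 49.37, 65.74, 76.97]
        b = [70.10, 80.02, 77.51, 79.95, 45.00, 50.30, 44.12, 48.88, 60.11, 75.20]
        d = np.array(a) - np.array(b)
        expect_t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        t, df, p = paired_t(a, b)
        assert t == pytest.approx(expect_t, abs=1e-12)
        assert df == 9
        from scipy import stats as sps

        assert p == pytest.approx(2 * sps.t.sf(abs(expect_t), 9), abs=1e-12)
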