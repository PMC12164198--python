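import math

import numpy as np
import pytest

from mrscreen.mr_estimators import (
    MethodResult,
    egger,
    ivw,
    mr_presso,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrscreen.sumstats_io import HarmonizedVariant
from mrscreen.synthetic_data import SimScenario, TruthRecord, harmonized_from_sim, simulate_pair
from tests.conftest import make_harmonized, random_harmonized


def wls_oracle(bx, by, w, intercept=True):
    """Independent weighted-least-squares oracle via numpy lstsq."""
    bx, by, w = map(np.asarray, (bx, by, w))
    if intercept:
        design = np.column_stack([np.ones_like(bx), bx])
    else:
        design = bx[:, None]
    a = design * np.sqrt(w)[:, None]
    b = by * np.sqrt(w)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol


class TestWaldRatio:
    def test_arithmetic(self):
        v = HarmonizedVariant("rs1", 0.5, 0.05, 1e-8, 0.25, 0.1, 0.1)
        r = wald_ratio(v)
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)

    def test_null_numerator(self):
        v = HarmonizedVariant("rs1", 0.5, 0.05, 1e-8, 0.0, 0.1, 1.0)
        r = wald_ratio(v)
        assert r.estimate == 0.0
        assert r.pval == 1.0

    def test_zero_exposure_beta_errors(self):
        v = HarmonizedVariant("rs1", 0.0, 0.05, 1e-8, 0.1, 0.1, 0.1)
        with pytest.raises(ZeroDivisionError):
            wald_ratio(v)


class TestIvw:
    def test_three_point_fixture(self, three_point_set):
        # weights beta_exp^2/se_out^2 are all 100; estimate = (50+60+46.6667)/300
        r = ivw(three_point_set, mode="fixed")
        assert r.estimate == pytest.approx(0.522222, abs=1e-6)
        assert r.se == pytest.approx(0.057735, abs=1e-6)

    def test_exact_ratios_give_exact_estimate(self, exact_ratio_set):
        fixed = ivw(exact_ratio_set, mode="fixed")
        rand = ivw(exact_ratio_set, mode="multiplicative_random")
        assert fixed.estimate == pytest.approx(0.4, abs=1e-12)
        assert fixed.se == rand.se  # Q = 0 -> truncated at 1

    def test_single_variant_equals_wald(self):
        hs = make_harmonized(bx=[0.2], by=[0.1], sy=[0.05])
        r = ivw(hs)
        w = wald_ratio(hs.variants[0])
        assert (r.estimate, r.se, r.pval) == (w.estimate, w.se, w.pval)

    def test_empty_errors(self):
        hs = make_harmonized(bx=[], by=[], sy=[])
        with pytest.raises(ValueError):
            ivw(hs)

    def test_random_se_never_below_fixed(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            hs = random_harmonized(rng)
            assert ivw(hs).se >= ivw(hs, mode="fixed").se

    def test_matches_zero_intercept_wls_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            hs = random_harmonized(rng)
            bx, _, by, sy = hs.arrays()
            (slope,) = wls_oracle(bx, by, 1 / sy**2, intercept=False)
            assert ivw(hs).estimate == pytest.approx(slope, abs=1e-10)


class TestEgger:
    def test_exact_fit_recovers_slope_and_zero_intercept(self, exact_ratio_set):
        e = egger(exact_ratio_set)
        assert e.slope.estimate == pytest.approx(0.4, abs=1e-10)
        assert e.intercept == pytest.approx(0.0, abs=1e-10)

    def test_three_point_fixture_matches_wls_oracle(self, three_point_set):
        bx, _, by, sy = three_point_set.arrays()
        intercept, slope = wls_oracle(bx, by, 1 / sy**2)
        e = egger(three_point_set)
        assert e.slope.estimate == pytest.approx(slope, abs=1e-12)
        assert e.intercept == pytest.approx(intercept, abs=1e-12)
        # frozen values from the oracle
        assert e.slope.estimate == pytest.approx(0.5269230769, abs=1e-9)
        assert e.intercept == pytest.approx(-0.0007692308, abs=1e-9)

    def test_orientation_symmetry(self, three_point_set):
        flipped = make_harmonized(
            bx=[-0.1, 0.2, 0.3], by=[-0.05, 0.12, 0.14], sy=[0.01, 0.02, 0.03]
        )
        e1, e2 = egger(three_point_set), egger(flipped)
        assert e1.slope == e2.slope
        assert e1.intercept == pytest.approx(e2.intercept)
        assert e1.intercept_pval == pytest.approx(e2.intercept_pval)

    def test_matches_oracle_after_orientation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            hs = random_harmonized(rng)
            bx, _, by, sy = hs.arrays()
            sign = np.where(bx < 0, -1.0, 1.0)
            intercept, slope = wls_oracle(sign * bx, sign * by, 1 / sy**2)
            e = egger(hs)
            assert e.slope.estimate == pytest.approx(slope, abs=1e-10)
            assert e.intercept == pytest.approx(intercept, abs=1e-10)

    def test_too_few_variants(self):
        hs = make_harmonized(bx=[0.1, 0.2], by=[0.05, 0.1], sy=[0.01, 0.01])
        with pytest.raises(ValueError):
            egger(hs)


class TestWeightedMedian:
    def test_interpolation_fixture(self):
        # equal weights: cumulative p-grid {1/6, 1/2, 5/6} crosses 0.5 at the
        # middle sorted ratio
        hs = make_harmonized(
            bx=[1.0, 1.0, 1.0], by=[0.5, 0.6, 0.4667], sy=[0.1] * 3
        )
        r = weighted_median(hs, n_boot=50, seed=0)
        assert r.estimate == pytest.approx(0.5)

    def test_majority_weight_breakdown(self):
        # >50% of weight at ratio 0.3: estimate sticks to the majority
        hs = make_harmonized(
            bx=[1.0, 1.0, 1.0, 1.0, 1.0],
            by=[0.3, 0.3, 0.3, 5.0, -4.0],
            sy=[0.05, 0.05, 0.05, 0.5, 0.5],
        )
        r = weighted_median(hs, n_boot=50, seed=0)
        assert r.estimate == pytest.approx(0.3, abs=1e-9)

    def test_seed_determinism(self, three_point_set):
        a = weighted_median(three_point_set, seed=123)
        b = weighted_median(three_point_set, seed=123)
        c = weighted_median(three_point_set, seed=124)
        assert a == b
        assert a.se != c.se

    def test_between_min_and_max_ratio(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            hs = random_harmonized(rng)
            bx, _, by, _ = hs.arrays()
            ratios = by / bx
            r = weighted_median(hs, n_boot=20, seed=0)
            assert ratios.min() - 1e-12 <= r.estimate <= ratios.max() + 1e-12

    def test_equal_weights_odd_k_is_plain_median(self):
        rng = np.random.default_rng(9)
        by = rng.normal(0.1, 0.3, 5)
        hs = make_harmonized(bx=np.ones(5), by=by, sy=np.full(5, 0.2))
        r = weighted_median(hs, n_boot=20, seed=0)
        assert r.estimate == pytest.approx(np.median(by))

    def test_too_few_variants(self):
        hs = make_harmonized(bx=[0.1, 0.2], by=[0.05, 0.1], sy=[0.01, 0.01])
        with pytest.raises(ValueError):
            weighted_median(hs)


class TestMrPresso:
    def test_k3_not_testable(self):
        hs = make_harmonized(bx=[0.1, 0.2, 0.3], by=[0.05, 0.1, 0.15], sy=[0.01] * 3)
        res = mr_presso(hs, seed=0)
        assert not res.testable
        assert res.global_pval is None

    def test_planted_outlier_flagged_and_corrected(self):
        scn = SimScenario(k=15, h2_exposure=0.3, swap_fraction=0)
        truth = TruthRecord(theta=0.4, n_exp=50000, seed=21)
        pair = simulate_pair(scn, truth)
        hs = harmonized_from_sim(pair)
        v = hs.variants[4]
        hs.variants[4] = HarmonizedVariant(
            v.variant_id, v.beta_exp, v.se_exp, v.pval_exp,
            v.beta_out + 10 * v.se_out, v.se_out, v.pval_out,
        )
        res = mr_presso(hs, n_sim=1000, seed=1)
        assert 4 in res.outlier_indices
        assert res.corrected is not None
        assert abs(res.corrected.estimate - 0.4) < abs(res.raw.estimate - 0.4)
        assert res.global_pval < 0.05
        assert res.distortion_pval is not None

    def test_homogeneous_sets_rarely_reject(self):
        # global test keeps its level on null data across replicate datasets
        rejections = 0
        n_data = 50
        for rep in range(n_data):
            scn = SimScenario(k=10, h2_exposure=0.2, swap_fraction=0)
            truth = TruthRecord(theta=0.2, n_exp=20000, seed=1000 + rep)
            hs = harmonized_from_sim(simulate_pair(scn, truth))
            res = mr_presso(hs, n_sim=1000, seed=rep)
            rejections += res.global_pval <= 0.05
        assert rejections / n_data <= 0.10

    def test_seed_determinism(self):
        scn = SimScenario(k=8, swap_fraction=0)
        hs = harmonized_from_sim(simulate_pair(scn, TruthRecord(seed=5)))
        a = mr_presso(hs, seed=9)
        b = mr_presso(hs, seed=9)
        assert a == b

    def test_global_p_superuniform_under_null(self):
        # type-I error of the global test at alpha=0.05 over 200 null replicates
        rejections = 0
        n_data = 200
        scn = SimScenario(k=10, h2_exposure=0.25, swap_fraction=0)
        for rep in range(n_data):
            truth = TruthRecord(theta=0.3, n_exp=30000, seed=40_000 + rep)
            hs = harmonized_from_sim(simulate_pair(scn, truth))
            res = mr_presso(hs, n_sim=300, seed=rep)
            rejections += res.global_pval <= 0.05
        assert rejections / n_data <= 0.07


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_outcome_scaling_scales_estimates(self, three_point_set, c):
        bx, _, by, sy = three_point_set.arrays()
        scaled = make_harmonized(bx=bx, by=c * by, sy=c * sy)
        for fn in (lambda h: ivw(h), lambda h: egger(h).slope):
            base, new = fn(three_point_set), fn(scaled)
            assert new.estimate == pytest.approx(c * base.estimate)
            assert new.se == pytest.approx(c * base.se)
        wm0 = weighted_median(three_point_set, n_boot=200, seed=4)
        wm1 = weighted_median(scaled, n_boot=200, seed=4)
        assert wm1.estimate == pytest.approx(c * wm0.estimate)
        assert wm1.se == pytest.approx(c * wm0.se)


class TestConvergence:
    def test_all_estimators_converge_with_tiny_se(self):
        rng = np.random.default_rng(13)
        bx = rng.uniform(0.1, 0.3, 10)
        hs = make_harmonized(
            bx=bx, by=0.25 * bx, sy=np.full(10, 1e-6), sx=np.full(10, 1e-6)
        )
        estimates = [
            ivw(hs).estimate,
            egger(hs).slope.estimate,
            weighted_median(hs, n_boot=100, seed=0).estimate,
            mr_presso(hs, n_sim=100, seed=0).raw.estimate,
        ]
        assert all(e == pytest.approx(0.25, abs=1e-6) for e in estimates)


class TestToOddsRatio:
    def test_identity(self):
        m = MethodResult("ivw", 0.0, 1.0, -1.96, 1.96, 1.0, 3)
        or_, _ = to_odds_ratio(m)
        assert or_ == 1.0

    def test_or_and_lnor_are_consistent(self):
        # ln(0.472) = -0.7506; exponentiating -0.7508 reproduces 0.472
        assert math.log(0.472) == pytest.approx(-0.7508, abs=5e-4)
        m = MethodResult("presso", -0.7508, 0.2, -0.7508 - 0.392, -0.7508 + 0.392, 0.001, 13)
        or_, (lo, hi) = to_odds_ratio(m)
        assert or_ == pytest.approx(0.472, abs=5e-4)
        assert lo < or_ < hi

    def test_exp_display(self):
        m = MethodResult("ivw", 1.121, 0.5, 0.141, 2.101, 0.02, 5)
        or_, _ = to_odds_ratio(m)
        assert or_ == pytest.approx(3.068, abs=1e-3)
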