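"""Causal estimators: worked examples, invariances, simulation behaviour."""

import math

import numpy as np
import pytest
from scipy import stats

from mr2s.errors import (DegenerateInstrumentError, DomainError,
                         InsufficientDataError)
from mr2s.harmonize import HarmonizedPair
from mr2s.mr_core import (MREstimate, cochrans_q, ivw, mr_egger,
                          select_main_method, wald_ratio, weighted_median,
                          weighted_mode)

from conftest import make_pairs


class TestWaldRatio:
    def test_worked_example(self):
        est = wald_ratio(HarmonizedPair("rs1", 0.2, 0.01, 0.1, 0.05))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.25)
        assert est.n_snps == 1
        assert est.ci_low == pytest.approx(0.5 - 1.96 * 0.25)

    def test_zero_outcome_effect(self):
        est = wald_ratio(HarmonizedPair("rs1", 0.2, 0.01, 0.0, 0.05))
        assert est.beta == 0.0 and est.pval == pytest.approx(1.0)

    def test_orientation_invariance(self):
        a = wald_ratio(HarmonizedPair("rs1", 0.2, 0.01, 0.1, 0.05))
        b = wald_ratio(HarmonizedPair("rs1", -0.2, 0.01, -0.1, 0.05))
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_degenerate_instrument(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(HarmonizedPair("rs1", 0.0, 0.01, 0.1, 0.05))


class TestIVW:
    def test_hand_worked_fixed_effects(self, two_pair_dataset):
        est = ivw(two_pair_dataset, "fixed")
        assert est.beta == pytest.approx(0.34, rel=1e-12)
        assert est.se == pytest.approx(1 / math.sqrt(500), rel=1e-12)
        assert est.q_stat == pytest.approx(3.2, rel=1e-9)

    def test_k1_reduces_to_wald_bitwise(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            bx = float(rng.uniform(-1, 1)) or 0.1
            by = float(rng.uniform(-1, 1))
            sy = float(rng.uniform(0.001, 1))
            pair = HarmonizedPair("rs1", bx, 1e-3, by, sy)
            w = wald_ratio(pair)
            f = ivw([pair], "fixed")
            assert f.beta == w.beta and f.se == w.se and f.pval == w.pval

    def test_homogeneous_ratios_give_zero_q(self):
        pairs = make_pairs([1.0, 2.0, 4.0], [0.3, 0.6, 1.2], [0.1, 0.1, 0.1])
        fe = ivw(pairs, "fixed")
        mre = ivw(pairs, "multiplicative_random")
        assert fe.beta == pytest.approx(0.3)
        assert fe.q_stat == pytest.approx(0.0, abs=1e-20)
        assert mre.se == fe.se  # overdispersion floored at 1

    def test_mre_inflates_se_under_heterogeneity(self):
        pairs = make_pairs([1.0, 1.0, 1.0, 1.0], [0.1, 0.5, 0.9, 1.3],
                           [0.05] * 4)
        fe = ivw(pairs, "fixed")
        mre = ivw(pairs, "multiplicative_random")
        assert mre.beta == fe.beta
        assert mre.se == pytest.approx(fe.se * math.sqrt(fe.q_stat / 3))
        assert mre.se > fe.se

    def test_orientation_invariance(self, two_pair_dataset):
        flipped = [HarmonizedPair(p.variant_id, -p.beta_exp, p.se_exp,
                                  -p.beta_out, p.se_out)
                   for p in two_pair_dataset]
        a, b = ivw(two_pair_dataset, "fixed"), ivw(flipped, "fixed")
        assert a.beta == pytest.approx(b.beta) and a.se == pytest.approx(b.se)

    def test_scale_equivariance(self, two_pair_dataset):
        c = 3.7
        scaled = [HarmonizedPair(p.variant_id, p.beta_exp, p.se_exp,
                                 c * p.beta_out, c * p.se_out)
                  for p in two_pair_dataset]
        a, b = ivw(two_pair_dataset, "fixed"), ivw(scaled, "fixed")
        assert b.beta == pytest.approx(c * a.beta)
        assert b.se == pytest.approx(c * a.se)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            ivw([], "fixed")
        with pytest.raises(InsufficientDataError):
            ivw(make_pairs([1.0], [0.3], [0.1]), "multiplicative_random")

    def test_zero_exposure_effect_named(self):
        pairs = make_pairs([1.0, 0.0], [0.3, 0.1], [0.1, 0.1])
        with pytest.raises(DegenerateInstrumentError, match="rs2"):
            ivw(pairs, "fixed")


class TestCochransQ:
    def test_hand_worked(self, two_pair_dataset):
        q, df, p = cochrans_q(two_pair_dataset, 0.34)
        assert q == pytest.approx(3.2, rel=1e-9)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(3.2, 1))

    def test_homogeneous(self):
        pairs = make_pairs([1.0, 2.0], [0.3, 0.6], [0.1, 0.1])
        q, _, p = cochrans_q(pairs, 0.3)
        assert q == pytest.approx(0.0, abs=1e-20) and p == pytest.approx(1.0)

    def test_needs_two(self):
        with pytest.raises(InsufficientDataError):
            cochrans_q(make_pairs([1.0], [0.3], [0.1]), 0.3)

    def test_null_distribution_matches_chi_square(self):
        # no pleiotropy, negligible exposure noise: Q about IVW center is
        # chi-square with k-1 degrees of freedom
        rng = np.random.default_rng(5)
        k, reps = 10, 400
        qs = []
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.15, k)
            sy = np.full(k, 0.02)
            by = 0.3 * bx + rng.normal(0, sy)
            pairs = make_pairs(bx, by, sy)
            est = ivw(pairs, "fixed")
            qs.append(est.q_stat)
        mean_q = float(np.mean(qs))
        # MC error of the mean ~ sqrt(2(k-1)/reps) ~ 0.21
        assert mean_q == pytest.approx(k - 1, abs=0.7)


class TestMREgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.02 + 0.5 * bx
        pairs = make_pairs(bx, by, [0.03, 0.02, 0.04, 0.03])
        slope, intercept = mr_egger(pairs)
        assert slope.beta == pytest.approx(0.5, rel=1e-9)
        assert intercept.beta == pytest.approx(0.02, rel=1e-9)

    def test_negative_exposure_effects_flipped_first(self):
        bx = np.array([0.05, -0.1, 0.15, -0.2])
        by = 0.02 * np.sign(bx) + 0.5 * bx
        pairs = make_pairs(bx, by, [0.03] * 4)
        slope, intercept = mr_egger(pairs)
        assert slope.beta == pytest.approx(0.5, rel=1e-9)
        assert intercept.beta == pytest.approx(0.02, rel=1e-9)

    def test_balanced_pleiotropy_gives_null_intercept(self):
        rng = np.random.default_rng(11)
        k, reps = 30, 300
        intercepts = []
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.3, k)
            alpha = rng.normal(0.0, 0.02, k)
            sy = np.full(k, 0.01)
            by = 0.3 * bx + alpha + rng.normal(0, sy)
            _, inter = mr_egger(make_pairs(bx, by, sy))
            intercepts.append(inter.beta)
        # mean intercept ~ 0 within Monte-Carlo error of the mean
        mc_se = np.std(intercepts) / math.sqrt(reps)
        assert abs(np.mean(intercepts)) < 4 * mc_se + 1e-4

    def test_directional_pleiotropy_under_inside_slope_beats_ivw(self):
        rng = np.random.default_rng(13)
        k, reps, theta = 40, 200, 0.3
        egger_err, ivw_err = [], []
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.3, k)
            alpha = rng.normal(0.05, 0.01, k)  # InSIDE holds: alpha indep of bx
            sy = np.full(k, 0.01)
            by = theta * bx + alpha + rng.normal(0, sy)
            pairs = make_pairs(bx, by, sy)
            slope, _ = mr_egger(pairs)
            egger_err.append(slope.beta - theta)
            ivw_err.append(ivw(pairs, "fixed").beta - theta)
        assert abs(np.mean(egger_err)) < abs(np.mean(ivw_err))

    def test_needs_three_and_varying_exposure(self):
        with pytest.raises(InsufficientDataError):
            mr_egger(make_pairs([1.0, 2.0], [0.3, 0.6], [0.1, 0.1]))
        with pytest.raises(DomainError):
            mr_egger(make_pairs([0.1, 0.1, 0.1], [0.1, 0.2, 0.3], [0.1] * 3))


class TestWeightedMedian:
    def test_equal_weight_median(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.1] * 3)
        est = weighted_median(pairs, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_all_ratios_equal_and_bootstrap_se_shrinks(self):
        big = weighted_median(make_pairs([1.0, 2.0, 4.0], [0.3, 0.6, 1.2],
                                         [0.05] * 3), n_boot=200, seed=1)
        small = weighted_median(make_pairs([1.0, 2.0, 4.0], [0.3, 0.6, 1.2],
                                           [1e-6] * 3), n_boot=200, seed=1)
        assert big.beta == pytest.approx(0.3)
        assert small.beta == pytest.approx(0.3)
        assert small.se < big.se

    def test_majority_valid_resists_invalid_minority(self):
        rng = np.random.default_rng(21)
        theta, reps = 0.3, 60
        wm_err, ivw_err = [], []
        for _ in range(reps):
            bx = rng.uniform(0.1, 0.3, 14)
            sy = np.full(14, 0.01)
            by = theta * bx + rng.normal(0, sy)
            by[10:] += 0.5 * bx[10:]  # 4 invalid: ratios shifted to 0.8
            pairs = make_pairs(bx, by, sy)
            wm_err.append(weighted_median(pairs, n_boot=10,
                                          seed=2).beta - theta)
            ivw_err.append(ivw(pairs, "fixed").beta - theta)
        assert abs(np.mean(wm_err)) < 0.03
        assert np.mean(ivw_err) > 0.08  # IVW dragged upward
        assert abs(np.mean(wm_err)) < abs(np.mean(ivw_err))

    def test_seeded_bootstrap_reproducible(self):
        pairs = make_pairs([1.0, 1.5, 2.0], [0.3, 0.5, 0.7], [0.05] * 3)
        a = weighted_median(pairs, n_boot=100, seed=7)
        b = weighted_median(pairs, n_boot=100, seed=7)
        assert a.se == b.se

    def test_needs_three(self):
        with pytest.raises(InsufficientDataError):
            weighted_median(make_pairs([1.0, 2.0], [0.3, 0.6], [0.1] * 2),
                            n_boot=10, seed=0)


class TestWeightedMode:
    def test_all_ratios_equal(self):
        est = weighted_mode(make_pairs([1.0, 2.0, 4.0], [0.3, 0.6, 1.2],
                                       [0.05] * 3), n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.3)

    def test_cluster_beats_outliers(self):
        bx = np.ones(10)
        by = np.array([0.28, 0.29, 0.3, 0.3, 0.31, 0.32, 0.3, 1.0, 1.02, 0.98])
        est = weighted_mode(make_pairs(bx, by, [0.05] * 10), n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.3, abs=0.05)

    def test_symmetric_tie_breaks_to_smaller_mode(self):
        bx = np.ones(6)
        by = np.array([0.1, 0.1, 0.1, 0.9, 0.9, 0.9])
        est = weighted_mode(make_pairs(bx, by, [0.05] * 6), n_boot=20, seed=0)
        assert est.beta < 0.5  # deterministic tie-break to the smaller mode

    def test_needs_three(self):
        with pytest.raises(InsufficientDataError):
            weighted_mode(make_pairs([1.0, 2.0], [0.3, 0.6], [0.1] * 2),
                          n_boot=10, seed=0)


class TestMethodPlan:
    @pytest.mark.parametrize("k,main,sens", [
        (1, "wald_ratio", ()),
        (2, "ivw_fe", ()),
        (3, "ivw_fe", ()),
        (4, "ivw_mre", ("weighted_median", "mr_egger")),
        (20, "ivw_mre", ("weighted_median", "mr_egger")),
    ])
    def test_rules(self, k, main, sens):
        plan = select_main_method(k)
        assert plan.main == main and plan.sensitivity == sens

    def test_zero_instruments(self):
        with pytest.raises(InsufficientDataError):
            select_main_method(0)

    def test_continuous_mode_same_rules(self):
        assert select_main_method(5, "continuous_pdff").main == "ivw_mre"
        with pytest.raises(DomainError):
            select_main_method(5, "nonsense")


class TestEstimateContracts:
    def test_ci_and_or_reporting(self):
        est = MREstimate("ivw_fe", beta=0.3148, se=0.12695, pval=0.013,
                         n_snps=5)
        assert est.ci_low == pytest.approx(0.3148 - 1.96 * 0.12695)
        assert est.odds_ratio == pytest.approx(math.exp(0.3148))
        lo, hi = est.or_ci
        assert lo < est.odds_ratio < hi

    def test_invalid_method_label(self):
        with pytest.raises(DomainError):
            MREstimate("magic", 0.0, 1.0, 0.5, 1)
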