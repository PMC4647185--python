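"""Discrimination and rule-out metrics: concordance-pair oracle for the
AUC, bootstrap model comparison, decile calibration, recalibration, and
fixed-sensitivity classification tables."""

import numpy as np
import pytest
from scipy.special import expit, logit

import bpscreen as b


def _brute_force_auc(scores, outcomes):
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, float)
    cases = s[y == 1]
    ctrl = s[y == 0]
    wins = ties = 0
    for c in cases:
        wins += np.sum(c > ctrl)
        ties += np.sum(c == ctrl)
    return (wins + 0.5 * ties) / (len(cases) * len(ctrl))


class TestAUC:
    def test_equals_concordance_pair_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 200))
            y = np.zeros(n)
            y[: max(1, int(rng.integers(1, n)))] = 1
            rng.shuffle(y)
            # ties included deliberately
            s = np.round(rng.normal(size=n), 1)
            assert b.auc_rank(s, y) == pytest.approx(
                _brute_force_auc(s, y), abs=1e-12)

    def test_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        a, (lo, hi) = b.auc(s, y)
        assert a == 1.0 and hi <= 1.0

    def test_uninformative_scores_near_half(self, rng):
        n = 4000
        y = (rng.random(n) < 0.3).astype(float)
        s = rng.normal(size=n)
        assert abs(b.auc_rank(s, y) - 0.5) < 0.03

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            b.auc_rank([0.1, 0.2], [1, 1])

    def test_ci_covers_point_estimate(self, rng):
        y = (rng.random(500) < 0.2).astype(float)
        s = rng.normal(size=500) + y
        a, (lo, hi) = b.auc(s, y)
        assert lo < a < hi


class TestCompareAUCBootstrap:
    def test_identical_scores_give_p_one(self, rng):
        y = (rng.random(300) < 0.2).astype(float)
        s = rng.normal(size=300) + y
        assert b.compare_auc_bootstrap(s, s, y, B=200, seed=1) == 1.0

    def test_monotone_transform_preserves_difference(self, rng):
        y = (rng.random(400) < 0.25).astype(float)
        s1 = rng.normal(size=400) + 1.5 * y
        s2 = rng.normal(size=400) + 0.3 * y
        p1 = b.compare_auc_bootstrap(s1, s2, y, B=300, seed=2)
        p2 = b.compare_auc_bootstrap(np.exp(s1), np.exp(s2), y, B=300, seed=2)
        assert p1 == pytest.approx(p2, abs=1e-12)  # ranks unchanged

    def test_detects_clear_improvement(self, rng):
        n = 2000
        y = (rng.random(n) < 0.15).astype(float)
        signal = rng.normal(size=n)
        s_good = signal + 2.0 * y
        s_bad = rng.normal(size=n)
        assert b.compare_auc_bootstrap(s_good, s_bad, y, B=300, seed=3) < 0.001

    def test_small_b_warns(self, rng):
        y = (rng.random(100) < 0.3).astype(float)
        s = rng.normal(size=100)
        with pytest.warns(UserWarning):
            b.compare_auc_bootstrap(s, s + 0.001, y, B=50, seed=4)


class TestCalibrationDeciles:
    def test_partition_into_tenths(self, rng):
        p = rng.random(1000)
        y = (rng.random(1000) < p).astype(float)
        tab = b.calibration_deciles(p, y)
        assert len(tab) == 10
        assert tab["n"].sum() == 1000
        assert tab["n"].max() - tab["n"].min() <= 1

    def test_constant_prediction_matches_prevalence(self, rng):
        n = 2000
        y = (rng.random(n) < 0.2).astype(float)
        p = np.full(n, 0.2)
        tab = b.calibration_deciles(p, y)
        assert np.allclose(tab["mean_predicted"], 0.2)
        assert abs(tab["observed"].mean() - 0.2) < 0.04

    def test_well_calibrated_model_covered_by_ci(self, rng):
        n = 10000
        p = expit(rng.normal(-2.0, 1.0, n))
        y = (rng.random(n) < p).astype(float)
        tab = b.calibration_deciles(p, y)
        covered = ((tab["ci_low"] <= tab["mean_predicted"])
                   & (tab["mean_predicted"] <= tab["ci_high"])).sum()
        assert covered >= 8

    def test_overestimation_shows_in_top_deciles(self, rng):
        n = 5000
        p = expit(rng.normal(-2.0, 1.0, n))
        y = (rng.random(n) < p).astype(float)
        tab = b.calibration_deciles(np.minimum(2 * p, 0.99), y)
        top = tab.iloc[-3:]
        assert (top["mean_predicted"] > top["observed"]).all()


class TestRecalibrate:
    def test_self_consistency(self, rng):
        n = 5000
        lp = rng.normal(-3.5, 1.2, n)
        y = (rng.random(n) < expit(lp)).astype(float)
        a, bb = b.recalibrate(lp, y)
        # crude SEs on this design are ~0.1; stay within a generous band
        assert abs(a) < 0.35 and abs(bb - 1.0) < 0.15

    def test_known_shift_recovery(self, rng):
        n = 5000
        lp = rng.normal(-3.0, 1.0, n)
        y = (rng.random(n) < expit(lp - 0.5)).astype(float)
        a, bb = b.recalibrate(lp, y)
        assert a == pytest.approx(-0.5, abs=0.3)
        assert bb == pytest.approx(1.0, abs=0.15)

    def test_mean_predicted_equals_prevalence_after_recalibration(self, rng):
        n = 4000
        lp = rng.normal(-2.5, 1.0, n)
        y = (rng.random(n) < expit(0.8 * lp - 0.7)).astype(float)
        a, bb = b.recalibrate(lp, y)
        assert expit(a + bb * lp).mean() == pytest.approx(y.mean(), abs=1e-6)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            b.recalibrate(np.zeros(100), np.r_[np.ones(10), np.zeros(90)])


class TestThresholdForSensitivity:
    def test_target_one_gives_min_case_score(self, rng):
        y = (rng.random(200) < 0.2).astype(float)
        s = rng.random(200)
        t = b.threshold_for_sensitivity(s, y, 1.0)
        assert t == s[y == 1].min()

    def test_ten_cases_at_95(self, rng):
        s = np.r_[rng.random(90), np.linspace(0.5, 0.95, 10)]
        y = np.r_[np.zeros(90), np.ones(10)]
        # ceil(9.5) = 10 cases must test positive -> min case score
        assert b.threshold_for_sensitivity(s, y, 0.95) == 0.5

    def test_monotone_in_target(self, rng):
        y = (rng.random(500) < 0.1).astype(float)
        s = rng.random(500)
        ts = [b.threshold_for_sensitivity(s, y, t)
              for t in (0.5, 0.8, 0.9, 0.95, 0.99)]
        assert all(a >= bb for a, bb in zip(ts, ts[1:]))

    def test_achieved_sensitivity_at_least_target(self, rng):
        y = (rng.random(300) < 0.15).astype(float)
        s = rng.random(300)
        for target in (0.8, 0.95, 0.99):
            t = b.threshold_for_sensitivity(s, y, target)
            sens = np.mean(s[y == 1] >= t)
            assert sens >= target


class TestClassificationMetrics:
    def test_printed_cohort_counts(self):
        """2x2 counts from a large published screening table reproduce the
        printed specificity / predictive values at printed rounding."""
        row = b.metrics_from_counts(tp=297, fp=8019, tn=4633, fn=16)
        assert row.sensitivity == pytest.approx(297 / 313, abs=1e-9)
        assert round(row.specificity, 2) == 0.37
        assert round(row.ppv, 2) == 0.04
        assert round(row.npv, 2) == 1.00
        assert row.n_positive == 8316
        assert row.n == 12965

    def test_extreme_threshold(self, rng):
        y = (rng.random(100) < 0.3).astype(float)
        s = rng.random(100)
        row = b.classification_metrics(s, y, -np.inf)
        assert row.sensitivity == 1.0 and row.specificity == 0.0

    def test_lr_identities(self, rng):
        for _ in range(10):
            y = (rng.random(400) < 0.25).astype(float)
            s = rng.normal(size=400) + y
            row = b.classification_metrics(s, y, float(np.median(s)))
            if row.lr_pos is not None:
                assert row.lr_pos == pytest.approx(
                    row.sensitivity / (1 - row.specificity))
            if row.lr_neg is not None:
                assert row.lr_neg == pytest.approx(
                    (1 - row.sensitivity) / row.specificity)

    def test_sensitivity_specificity_monotone_in_threshold(self, rng):
        y = (rng.random(500) < 0.2).astype(float)
        s = rng.random(500)
        rows = [b.classification_metrics(s, y, t)
                for t in np.linspace(0.05, 0.95, 10)]
        sens = [r.sensitivity for r in rows]
        spec = [r.specificity for r in rows]
        assert all(a >= bb for a, bb in zip(sens, sens[1:]))
        assert all(a <= bb for a, bb in zip(spec, spec[1:]))

    def test_counts_sum_to_population(self, rng):
        y = (rng.random(250) < 0.2).astype(float)
        s = rng.random(250)
        row = b.classification_metrics(s, y, 0.5)
        assert row.n == 250

    def test_zero_denominator_reported(self):
        row = b.metrics_from_counts(tp=5, fp=0, tn=10, fn=1)
        assert row.lr_pos is None
        assert "lr_pos" in row.undefined
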