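"""Normogram stage: normal-subset selection, mixed-model likelihood,
population trajectories and conditional normative values (BLUP-style
Gaussian conditioning), checked against directly assembled multivariate
normal oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bpscreen as b
from bpscreen.normogram import (NormogramFit, fixed_design, marginal_loglik,
                                random_design)
from bpscreen.splines import DEFAULT_KNOTS, rcs_basis


def _toy_fit(G=None, sigma2=25.0, n_random=3):
    beta = np.zeros(25)
    beta[0] = 80.0   # intercept
    beta[1] = 0.15   # linear trend
    beta[2] = 0.9    # first curvature term
    _, names = fixed_design(np.array([20.0]), np.array(["normal"]),
                            np.array([0.0]))
    if G is None:
        G = np.array([[40.0, -0.6, 0.1], [-0.6, 0.04, 0.0], [0.1, 0.0, 0.02]])
    return NormogramFit(stratum="nulliparous", knots=DEFAULT_KNOTS,
                        term_names=names, beta=beta, G=np.asarray(G),
                        sigma2=sigma2, n_random=n_random)


def _mvn_conditional(fit, cell, smoke, y0, ga0, ga1):
    """Brute-force conditioning of the explicit joint bivariate normal of
    (MAP(ga0), MAP(ga1)) assembled from (beta, G, sigma2)."""
    z0 = random_design(ga0, fit.knots, fit.n_random)[0]
    z1 = random_design(ga1, fit.knots, fit.n_random)[0]
    m0 = b.population_trajectory(fit, cell, smoke, ga0)
    m1 = b.population_trajectory(fit, cell, smoke, ga1)
    # observed value includes residual; predicted future mean does not
    v00 = z0 @ fit.G @ z0 + fit.sigma2
    c10 = z1 @ fit.G @ z0
    return m1 + c10 / v00 * (y0 - m0)


class TestConditionalNormative:
    def test_matches_mvn_oracle_over_grid(self):
        fit = _toy_fit()
        rng = np.random.default_rng(1)
        for _ in range(50):
            ga0 = rng.uniform(8, 17.9)
            ga1 = rng.uniform(20, 36)
            y0 = rng.uniform(60, 110)
            cell = rng.choice(["underweight", "normal", "overweight", "obese"])
            smoke = float(rng.integers(0, 2))
            got = b.conditional_normative(fit, cell, smoke, y0, ga0, ga1)
            want = _mvn_conditional(fit, cell, smoke, y0, ga0, ga1)
            assert got == pytest.approx(want, abs=1e-8)

    def test_population_mean_input_gives_population_trajectory(self):
        fit = _toy_fit()
        m0 = b.population_trajectory(fit, "normal", 0.0, 12.0)
        got = b.conditional_normative(fit, "normal", 0.0, m0, 12.0, 36.0)
        assert got == pytest.approx(
            b.population_trajectory(fit, "normal", 0.0, 36.0))

    def test_zero_G_means_no_shrinkage_source(self):
        fit = _toy_fit(G=np.zeros((3, 3)))
        for y0 in (60.0, 85.0, 120.0):
            got = b.conditional_normative(fit, "normal", 0.0, y0, 12.0, 28.0)
            assert got == pytest.approx(
                b.population_trajectory(fit, "normal", 0.0, 28.0))

    def test_linear_in_initial_map_with_bounded_shrinkage(self):
        """The conditional normative is linear in the initial value with a
        slope bounded by the Cauchy-Schwarz limit sqrt(v_t / v_0); an
        arbitrary PSD G permits negative or >1 slopes, so the [0, 1) range
        is asserted only for realistic trajectory covariances (below)."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            A = rng.normal(size=(3, 3)) * [6, 0.3, 0.2]
            G = A @ A.T
            sigma2 = rng.uniform(5, 40)
            fit = _toy_fit(G=G, sigma2=sigma2)
            y = [b.conditional_normative(fit, "normal", 0.0, v, 12.0, 31.0)
                 for v in (80.0, 81.0, 82.0)]
            slope = y[1] - y[0]
            assert slope == pytest.approx(y[2] - y[1], abs=1e-9)  # linearity
            z0 = random_design(12.0, DEFAULT_KNOTS, 3)[0]
            zt = random_design(31.0, DEFAULT_KNOTS, 3)[0]
            bound = np.sqrt((zt @ G @ zt) / (z0 @ G @ z0 + sigma2))
            assert abs(slope) <= bound + 1e-12

    def test_shrinkage_in_unit_interval_for_fitted_models(self,
                                                          small_normograms):
        """Fitted trajectory covariances give shrinkage slopes in [0, 1)."""
        for fit in small_normograms.values():
            for target in (20.0, 28.0, 36.0):
                y80 = b.conditional_normative(fit, "normal", 0.0, 80.0,
                                              12.0, target)
                y81 = b.conditional_normative(fit, "normal", 0.0, 81.0,
                                              12.0, target)
                assert 0.0 <= y81 - y80 < 1.0

    def test_sigma2_to_zero_limit(self):
        G = np.array([[40.0, -0.6, 0.1], [-0.6, 0.04, 0.0], [0.1, 0.0, 0.02]])
        z0 = random_design(12.0, DEFAULT_KNOTS, 3)[0]
        zt = random_design(31.0, DEFAULT_KNOTS, 3)[0]
        expected_slope = (zt @ G @ z0) / (z0 @ G @ z0)
        fit = _toy_fit(G=G, sigma2=1e-10)
        y80 = b.conditional_normative(fit, "normal", 0.0, 80.0, 12.0, 31.0)
        y81 = b.conditional_normative(fit, "normal", 0.0, 81.0, 12.0, 31.0)
        assert (y81 - y80) == pytest.approx(expected_slope, abs=1e-6)

    def test_degenerate_variance_raises(self):
        fit = _toy_fit(G=np.zeros((3, 3)), sigma2=0.0)
        with pytest.raises(b.normogram.ModelIntegrityError):
            b.conditional_normative(fit, "normal", 0.0, 80.0, 12.0, 31.0)


class TestPopulationTrajectory:
    def test_reference_cell_is_beta_dot_basis(self):
        fit = _toy_fit()
        ga = 27.3
        basis = rcs_basis(ga)
        want = fit.beta[0] + fit.beta[1:5] @ basis
        assert b.population_trajectory(fit, "normal", 0.0, ga) == \
            pytest.approx(want)

    def test_smoking_contrast_is_main_effect_plus_interactions(self):
        fit = _toy_fit()
        fit.beta = np.arange(25, dtype=float) / 10
        ga = 30.0
        basis = rcs_basis(ga)
        names = fit.term_names
        want = fit.beta[names.index("smoking")] + sum(
            fit.beta[names.index(f"smoking:t{j+1}")] * basis[j]
            for j in range(4))
        diff = (b.population_trajectory(fit, "normal", 1.0, ga)
                - b.population_trajectory(fit, "normal", 0.0, ga))
        assert diff == pytest.approx(want)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            b.population_trajectory(_toy_fit(), "plump", 0.0, 30.0)


class TestMarginalLikelihood:
    def test_equals_direct_mvn_density_on_small_instance(self):
        """<=5 women x 3 visits: likelihood equals the per-woman joint
        normal density computed independently with scipy."""
        fit = _toy_fit()
        df = b.simulate_from_normogram(fit, 5, seed=3,
                                       nominal_visits=(24, 32))
        got = marginal_loglik(fit, df)
        want = 0.0
        for _, g in df.groupby("id"):
            X, _ = fixed_design(g["ga"].to_numpy(),
                                g["bmi_category"].to_numpy(),
                                g["smoking"].to_numpy(), fit.knots)
            Z = random_design(g["ga"].to_numpy(), fit.knots, 3)
            V = Z @ fit.G @ Z.T + fit.sigma2 * np.eye(len(g))
            want += stats.multivariate_normal.logpdf(
                g["map"].to_numpy(), mean=X @ fit.beta, cov=V)
        assert got == pytest.approx(want, abs=1e-8)

    def test_fitted_likelihood_not_below_truth(self):
        """ML optimum must dominate the generating parameters."""
        truth = _toy_fit()
        df = b.simulate_from_normogram(truth, 300, seed=11)
        fitted = b.fit_multilevel(df, min_women=100)
        assert marginal_loglik(fitted, df) >= marginal_loglik(truth, df) - 1e-3


class TestNormalSubset:
    def test_exclusions(self, small_derived):
        mask = b.normal_subset_mask(small_derived)
        sub = small_derived[mask]
        assert (sub["pe"] == 0).all()
        assert (sub["essential_htn"] == 0).all()
        assert (sub["diabetes"] == 0).all()
        assert (sub["ga_delivery"] >= 37).all()
        # roughly the target share of a population cohort
        assert 0.6 < mask.mean() < 0.8

    def test_flagging_one_diabetic_shrinks_subset_by_one(self, small_derived):
        mask0 = b.normal_subset_mask(small_derived)
        d2 = small_derived.copy()
        idx = d2[mask0].index[0]
        d2.loc[idx, "diabetes"] = 1.0
        mask1 = b.normal_subset_mask(d2)
        assert mask0.sum() - mask1.sum() == 1

    def test_all_case_cohort_errors(self, small_derived):
        d2 = small_derived.copy()
        d2["pe"] = 1.0
        with pytest.raises(ValueError):
            b.normal_subset_mask(d2)


class TestFittedNormograms:
    def test_convergence_and_shapes(self, small_normograms):
        for stratum, fit in small_normograms.items():
            assert fit.converged
            assert fit.sigma2 > 0
            eig = np.linalg.eigvalsh(fit.G)
            assert eig.min() > -1e-8
            assert len(fit.beta) == len(fit.term_names) == 25

    def test_population_curve_tracks_cell_means(self, small_cohort,
                                                small_derived,
                                                small_normograms):
        """Fitted reference-cell curve agrees with empirical cell means."""
        cohort, _ = small_cohort
        fit = small_normograms["nulliparous"]
        mask = b.normal_subset_mask(small_derived)
        ids = set(small_derived.loc[mask, "id"])
        gas, maps = [], []
        for p in cohort:
            if p.id in ids and p.parity == "0" and not p.smoking \
                    and p.bmi_category == "normal":
                for v in p.visits:
                    gas.append(v.ga)
                    maps.append(v.map)
        gas, maps = np.asarray(gas), np.asarray(maps)
        for lo, hi in [(19, 23), (27, 31), (33, 37)]:
            m = (gas >= lo) & (gas < hi)
            pred = np.mean([b.population_trajectory(fit, "normal", 0.0, g)
                            for g in gas[m]])
            assert abs(pred - maps[m].mean()) < 1.0

    def test_mean_deviation_near_zero_on_normal_subset(self, small_derived,
                                                       small_normograms):
        """The normogram is calibrated: deviations centre on zero."""
        mask = b.normal_subset_mask(small_derived)
        dn = b.add_normative_columns(small_derived[mask], small_normograms)
        for g in (20, 28, 36):
            dev = dn[f"deviation_{g}"].dropna()
            se = dev.std() / np.sqrt(len(dev))
            assert abs(dev.mean()) < max(4 * se, 0.5)

    def test_deviation_identity(self, small_derived, small_normograms):
        dn = b.add_normative_columns(small_derived, small_normograms)
        ok = dn.dropna(subset=["map_28", "expected_28"])
        np.testing.assert_allclose(ok["deviation_28"],
                                   ok["map_28"] - ok["expected_28"])
        # deviation missing iff observed missing
        assert dn.loc[dn["map_28"].isna(), "deviation_28"].isna().all()


def test_scale_equivariance_of_fit():
    """Doubling all MAP values doubles beta and quadruples G and sigma2."""
    truth = _toy_fit()
    df = b.simulate_from_normogram(truth, 250, seed=21)
    f1 = b.fit_multilevel(df, min_women=100)
    df2 = df.copy()
    df2["map"] = 2.0 * df2["map"]
    f2 = b.fit_multilevel(df2, min_women=100)
    np.testing.assert_allclose(f2.beta, 2.0 * f1.beta, rtol=2e-2, atol=0.05)
    assert f2.sigma2 == pytest.approx(4.0 * f1.sigma2, rel=2e-2)
    np.testing.assert_allclose(np.diag(f2.G), 4.0 * np.diag(f1.G),
                               rtol=0.15, atol=0.02)


def test_deviation_function():
    assert b.deviation(90.0, 85.0) == 5.0
    assert b.deviation(85.0, 85.0) == 0.0
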