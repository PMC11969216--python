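"""PGLS regression engine: oracle equivalence, invariances, group fits."""

import numpy as np
import pytest
from scipy import stats

import mutclock as mc

from conftest import dataset_xy, ols_normal_equations

# Frozen oracle: R nlme::gls(y ~ x, correlation = corBrownian(tree), method = "ML")
# on the 6-tip fixture tree and traits from conftest.  Coefficients, standard
# errors and ML log-likelihood frozen from that independent implementation.
R_GLS_COEF = (-8.002574444193, -0.929965529909)
R_GLS_SE = (0.0743976670305, 0.0391500564498)
R_GLS_LOGLIK = 5.71248324577


class TestFitPgls:
    def test_exact_interpolation(self, three_tip_tree):
        C = mc.brownian_vcv(three_tip_tree)
        x = np.array([0.0, 1.0, 2.0])
        y = 2.0 * x + 1.0
        fit = mc.fit_pgls(y, x, C, lam=1.0)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-20)

    def test_lambda_zero_equals_ols_oracle(self, small_dataset):
        _, table, tree = small_dataset
        y, x = dataset_xy(table)
        C = mc.brownian_vcv(tree)
        fit = mc.fit_pgls(y, x, C, lam=0.0)
        beta, se = ols_normal_equations(y, x)
        np.testing.assert_allclose(fit.coefficients, beta, rtol=1e-10)
        np.testing.assert_allclose(fit.standard_errors, se, rtol=1e-10)

    def test_matches_frozen_r_gls_oracle(self, six_tip_fit_inputs):
        """Pure-Brownian GLS coefficients, SEs and ML log-likelihood agree with
        an independent generalized-least-squares implementation (frozen)."""
        y, x, C = six_tip_fit_inputs
        fit = mc.fit_pgls(y, x, C, lam=1.0)
        np.testing.assert_allclose(fit.coefficients, R_GLS_COEF, rtol=1e-9)
        np.testing.assert_allclose(fit.standard_errors, R_GLS_SE, rtol=1e-9)
        assert fit.log_likelihood == pytest.approx(R_GLS_LOGLIK, abs=1e-8)

    def test_covariance_scale_invariance(self, six_tip_fit_inputs):
        y, x, C = six_tip_fit_inputs
        f1 = mc.fit_pgls(y, x, C, lam=1.0)
        scaled = mc.PhyloCovariance(C.matrix * 137.0, C.species_order)
        f2 = mc.fit_pgls(y, x, scaled, lam=1.0)
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, rtol=1e-10)
        np.testing.assert_allclose(f1.standard_errors, f2.standard_errors, rtol=1e-10)
        np.testing.assert_allclose(f1.p_values, f2.p_values, rtol=1e-9)
        assert f1.adjusted_r2 == pytest.approx(f2.adjusted_r2, rel=1e-10)

    def test_log_base_invariance_of_slope(self, six_tip_fit_inputs):
        """Rescaling both axes from log10 to natural log leaves the slope
        unchanged (slopes of log-log fits are base-invariant)."""
        y, x, C = six_tip_fit_inputs
        f10 = mc.fit_pgls(y, x, C, lam=1.0)
        fln = mc.fit_pgls(y * np.log(10), x * np.log(10), C, lam=1.0)
        assert fln.slope == pytest.approx(f10.slope, rel=1e-12)

    def test_lambda_ml_on_brownian_data_prefers_high_lambda(self):
        ds = mc.generate_dataset(mc.GeneratorConfig(n_species=100, seed=11))
        table, tree, _ = mc.match_to_tree(ds.rates_table(), ds.tree)
        y, x = dataset_xy(table)
        fit = mc.fit_pgls(y, x, mc.brownian_vcv(tree), lam="ml")
        assert fit.lam > 0.7  # data generated under pure Brownian residuals

    def test_degenerate_inputs_rejected(self, three_tip_tree):
        C = mc.brownian_vcv(three_tip_tree)
        with pytest.raises(mc.AnalysisError, match="constant predictor"):
            mc.fit_pgls(np.array([1.0, 2, 3]), np.ones(3), C)
        with pytest.raises(mc.AnalysisError):
            mc.fit_pgls(np.arange(4.0), np.arange(4.0), C)  # length mismatch


class TestFitGroups:
    def test_single_group_equals_global_fit(self, small_dataset):
        _, table, tree = small_dataset
        df = table.data.copy()
        df["group"] = "all"
        one = mc.RatesTable(df)
        gtab, skipped, fits = mc.fit_groups(one, tree, min_n=3)
        y, x = dataset_xy(table)
        global_fit = mc.fit_pgls(y, x, mc.brownian_vcv(tree))
        assert skipped == []
        assert len(gtab) == 1
        assert gtab.loc[0, "slope"] == pytest.approx(global_fit.slope, rel=1e-10)
        assert gtab.loc[0, "adjusted_r2"] == pytest.approx(global_fit.adjusted_r2, rel=1e-10)

    def test_small_groups_skipped_not_error(self, small_dataset):
        _, table, tree = small_dataset
        df = table.data.copy()
        df.loc[df.index[:2], "group"] = "tiny"
        gtab, skipped, _ = mc.fit_groups(mc.RatesTable(df), tree, min_n=3)
        assert ("tiny", 2) in skipped
        assert "tiny" not in set(gtab["group"])

    def test_two_groups_recover_common_slope(self):
        """Groups simulated under one shared slope both land within their
        95% CIs of the generating value."""
        cfg = mc.GeneratorConfig(n_species=80, n_groups=2, seed=3)
        ds = mc.generate_dataset(cfg)
        table, tree, _ = mc.match_to_tree(ds.rates_table(), ds.tree)
        _, _, fits = mc.fit_groups(table, tree, min_n=3)
        for fit in fits.values():
            half = stats.t.ppf(0.975, fit.df_residual) * fit.standard_errors[1]
            assert abs(fit.slope - cfg.true_slope) < half


class TestCompareFits:
    def test_identical_fits_give_zero_t(self, six_tip_fit_inputs):
        y, x, C = six_tip_fit_inputs
        fit = mc.fit_pgls(y, x, C)
        res = mc.compare_fits(fit, fit, "slope")
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_welch_construction_against_t_distribution(self, six_tip_fit_inputs):
        """est 1 +/- 1 vs -1 +/- 1 gives t = 2/sqrt(2); p follows the
        t-distribution with the Welch-Satterthwaite df."""
        y, x, C = six_tip_fit_inputs
        base = mc.fit_pgls(y, x, C)

        def fake(est, se, df):
            return mc.RegressionFit(
                coefficients=np.array([0.0, est]),
                standard_errors=np.array([1.0, se]),
                t_statistics=base.t_statistics,
                p_values=base.p_values,
                residual_variance=1.0,
                adjusted_r2=0.0,
                lam=1.0,
                n=df + 2,
                df_residual=df,
                log_likelihood=0.0,
            )

        res = mc.compare_fits(fake(1.0, 1.0, 1000), fake(-1.0, 1.0, 1000), "slope")
        assert res.t == pytest.approx(2.0 / np.sqrt(2.0), rel=1e-12)
        assert res.df == pytest.approx(2000.0, rel=1e-6)
        assert res.p == pytest.approx(2 * stats.t.sf(np.sqrt(2.0), res.df), rel=1e-12)


class TestDoublingEffect:
    @pytest.mark.parametrize(
        "slope,expected", [(0.0, 0.0), (-1.0, 50.0), (-0.71, 38.9)],
        ids=["no-effect", "halving", "study-slope"],
    )
    def test_values(self, slope, expected):
        assert mc.doubling_effect(slope) == pytest.approx(expected, abs=0.05)

    def test_positive_slope_gives_increase(self):
        assert mc.doubling_effect(1.0) == pytest.approx(-100.0)
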