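import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import metadrift as md
from metadrift.drift_correction import bspline_basis, evaluate_drift, fit_quantile_spline


def check_loss(y, fitted, tau):
    u = np.asarray(y, float) - np.asarray(fitted, float)
    return float(np.sum(u * (tau - (u < 0))))


def brute_force_minimum(x, y, tau, df, boundary):
    """Independent oracle: an optimal quantile-spline fit interpolates df
    points, so enumerate every df-subset, solve the interpolation exactly and
    take the smallest check loss."""
    design, _ = bspline_basis(np.asarray(x, float), df, boundary)
    n = len(y)
    best = np.inf
    for subset in itertools.combinations(range(n), df):
        sub = design[list(subset)]
        if abs(np.linalg.det(sub)) < 1e-12:
            continue
        beta = np.linalg.solve(sub, np.asarray(y, float)[list(subset)])
        best = min(best, check_loss(y, design @ beta, tau))
    return best


class TestFitQuantileSpline:
    def test_constant_y_interpolated(self):
        x = np.arange(1.0, 21.0)
        model = fit_quantile_spline(x, np.full(20, 7.5), df=6)
        np.testing.assert_allclose(evaluate_drift(model, x), 7.5, rtol=1e-8)
        assert model.objective == pytest.approx(0.0, abs=1e-7)

    def test_linear_y_reproduced(self):
        """The cubic basis nests linear functions, so a line is fit exactly."""
        x = np.arange(1.0, 31.0)
        y = 100.0 + 3.0 * x
        model = fit_quantile_spline(x, y, df=8)
        grid = np.linspace(1.0, 30.0, 97)
        np.testing.assert_allclose(evaluate_drift(model, grid), 100.0 + 3.0 * grid, rtol=1e-6)

    @pytest.mark.parametrize("tau", [0.5, 0.25])
    @pytest.mark.parametrize("seed", range(4))
    def test_objective_matches_brute_force(self, seed, tau):
        """Exact LP solution equals the enumeration oracle on small instances."""
        rng = np.random.default_rng(seed)
        n, df = 12, 4
        x = np.sort(rng.uniform(1, 50, n))
        y = 100 + 10 * np.sin(x / 8) + rng.normal(0, 3, n)
        model = fit_quantile_spline(x, y, tau=tau, df=df)
        oracle = brute_force_minimum(x, y, tau, df, (x.min(), x.max()))
        assert model.objective == pytest.approx(oracle, rel=1e-6, abs=1e-6)

    @pytest.mark.parametrize("tau", [0.25, 0.5, 0.75])
    def test_quantile_property_of_residuals(self, tau):
        """Subgradient optimality: at the optimum the number of negative
        residuals is at most tau*n + df and the number of positive residuals
        at most (1-tau)*n + df."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(30, 60))
            df = int(rng.integers(4, 17))
            x = np.sort(rng.uniform(1, 224, n))
            y = 1e4 * (1 + 0.3 * np.cos(x / 30)) * np.exp(rng.normal(0, 0.1, n))
            model = fit_quantile_spline(x, y, tau=tau, df=df)
            resid = y - evaluate_drift(model, x)
            assert (resid < -1e-9).sum() <= tau * n + model.df
            assert (resid > 1e-9).sum() <= (1 - tau) * n + model.df

    def test_too_few_points_falls_back_with_warning(self):
        x = np.arange(1.0, 11.0)
        y = 10.0 + x
        with pytest.warns(UserWarning, match="falling back"):
            model = fit_quantile_spline(x, y, df=16)
        assert model.df == max(4, len(x) // 3)

    def test_all_missing_errors(self):
        with pytest.raises(md.DriftCorrectionError, match="no QC intensities"):
            fit_quantile_spline([1.0, 2.0], [np.nan, np.nan])


class TestEvaluateDrift:
    def test_clamped_beyond_qc_bracket(self):
        x = np.arange(5.0, 26.0)
        y = 50.0 + 2.0 * x
        model = fit_quantile_spline(x, y, df=5, run_range=(1.0, 30.0))
        # beyond the last fitted order the curve is frozen at its boundary value
        assert evaluate_drift(model, 29.0) == pytest.approx(evaluate_drift(model, 25.0)[0])
        assert evaluate_drift(model, 1.5) == pytest.approx(evaluate_drift(model, 5.0)[0])


class TestCorrectFeature:
    def test_identity_when_qcs_constant(self, tiny_table):
        table, design = tiny_table
        model = fit_quantile_spline([1, 2, 3, 4, 5], [10.0] * 5, df=4, feature_id="F1")
        corrected = md.correct_feature("F1", table, design, model)
        np.testing.assert_allclose(corrected, table.intensities.loc["F1"], rtol=1e-9)

    def test_qcs_on_curve_become_constant(self):
        """Raw QCs lying exactly on the fitted curve collapse to qc_median.

        A linear intensity trend is inside the spline space, so the fit
        reproduces it exactly and the corrected QC CV is zero."""
        table, design, _ = md.simulate(
            md.SimulationConfig(seed=8, n_features=5, n_patients=10, noise_cv=0.0,
                                frac_system_peaks=0.0, frac_poorly_detected=0.0,
                                differential_spec=())
        )
        orders = design.orders(table.injections)
        for row, fid in enumerate(table.feature_ids):
            table.intensities.iloc[row] = 1e5 * (1.0 + 0.002 * orders)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrected, report, _ = md.correct_table(table, design)
        qc = corrected.intensities[design.qc_ids]
        cv = md.qc_cv_table(corrected, design)
        np.testing.assert_allclose(cv.to_numpy(), 0.0, atol=1e-6)
        for fid in corrected.feature_ids:
            med = np.median(table.intensities.loc[fid, design.qc_ids])
            np.testing.assert_allclose(qc.loc[fid], med, rtol=1e-6)


class TestCorrectTable:
    def test_zero_drift_zero_noise_identity(self):
        table, design, _ = md.simulate(
            md.SimulationConfig(seed=9, n_features=20, n_patients=4, noise_cv=0.0,
                                drift_amplitude_range=(0.0, 0.0),
                                frac_poorly_detected=0.0, differential_spec=())
        )
        corrected, report, _ = md.correct_table(table, design)
        pd.testing.assert_frame_equal(corrected.intensities, table.intensities,
                                      rtol=1e-9)

    def test_scale_equivariance(self, tiny_table):
        """Scaling a feature's raw row by c scales its corrected row by c."""
        table, design, truth = md.simulate(
            md.SimulationConfig(seed=10, n_features=8, n_patients=4, differential_spec=())
        )
        scaled = table.copy()
        scaled.intensities.iloc[2] *= 10.0
        c1, _, _ = md.correct_table(table, design)
        c2, _, _ = md.correct_table(scaled, design)
        fid = table.feature_ids[2]
        np.testing.assert_allclose(
            c2.intensities.loc[fid], 10.0 * c1.intensities.loc[fid], rtol=1e-9
        )
        other = table.feature_ids[3]
        np.testing.assert_allclose(
            c2.intensities.loc[other], c1.intensities.loc[other], rtol=1e-12
        )

    def test_median_cv_improves_in_every_seed(self):
        """Stochastic dominance: correction lowers the median QC CV, seed by seed."""
        for seed in range(6):
            table, design, _ = md.simulate(
                md.SimulationConfig(
                    seed=seed, n_features=150,
                    differential_spec=(md.DifferentialSpec("decreasing", 12, 1.0),),
                )
            )
            filtered = md.apply_filters(
                table, md.blank_filter(table, design), md.detection_filter(table, design)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, report, _ = md.correct_table(filtered, design)
            assert report.median_cv_after < report.median_cv_before

    def test_fitted_curve_recovers_injected_drift(self):
        """At low noise the fitted curve tracks the true drift within 3%."""
        for seed in range(10):
            cfg = md.SimulationConfig(
                seed=seed, n_features=30, noise_cv=0.02, differential_spec=(),
                frac_system_peaks=0.0, frac_poorly_detected=0.0,
            )
            table, design, truth = md.simulate(cfg)
            _, _, models = md.correct_table(table, design)
            qc_orders = design.orders(design.qc_ids)
            rel_rmse = []
            for fid, model in models.items():
                true_curve = (
                    truth.features.loc[fid, "baseline"]
                    * truth.drift.loc[fid, design.qc_ids].to_numpy(float)
                )
                fit_curve = evaluate_drift(model, qc_orders)
                rel_rmse.append(
                    np.sqrt(np.mean(((fit_curve - true_curve) / true_curve) ** 2))
                )
            assert np.median(rel_rmse) < 0.03
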