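"""Linear-plateau and linear dose-response fitting."""

import numpy as np
import pytest

import statsmodels.api as sm

from aquatrial import (
    DegenerateInputError,
    LinearPlateau,
    QuadraticPlateau,
    fit_linear,
    fit_linear_plateau,
    fit_quadratic_plateau,
)


def _plateau_data(b=80.0, slope=0.25, plateau=2.46, x=None):
    if x is None:
        x = np.linspace(72, 90, 12)
    y = plateau - slope * np.maximum(0.0, b - x)
    return x, y


class TestLinearPlateau:
    def test_noiseless_recovery_is_exact(self):
        x, y = _plateau_data()
        fit = fit_linear_plateau(x, y)
        assert fit.breakpoint == pytest.approx(80.0, abs=1e-6)
        assert fit.slope == pytest.approx(0.25, abs=1e-6)
        assert fit.plateau == pytest.approx(2.46, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.converged and not fit.plateau_only

    def test_constant_response_flagged_as_all_plateau(self):
        x = np.linspace(0, 10, 8)
        y = np.full_like(x, 3.5)
        fit = fit_linear_plateau(x, y)
        assert fit.plateau_only
        assert fit.slope == 0.0
        assert fit.plateau == pytest.approx(3.5)
        assert fit.breakpoint == pytest.approx(x.min())

    def test_estimates_invariant_to_point_order(self):
        rng = np.random.default_rng(3)
        x, y = _plateau_data()
        y = y + rng.normal(0, 0.05, x.size)
        perm = rng.permutation(x.size)
        a = fit_linear_plateau(x, y)
        b = fit_linear_plateau(x[perm], y[perm])
        assert b.breakpoint == pytest.approx(a.breakpoint, abs=1e-9)
        assert b.rss == pytest.approx(a.rss, rel=1e-12)

    def test_nested_within_single_line(self):
        # on rising data the plateau model can reproduce any nonneg-slope
        # line (breakpoint at max x), so its RSS cannot exceed the OLS line's
        rng = np.random.default_rng(9)
        x = np.linspace(0, 10, 20)
        y = 0.5 * x + rng.normal(0, 0.5, x.size)
        plateau_fit = fit_linear_plateau(x, y)
        line = fit_linear(x, y)
        line_rss = float(np.sum((y - line.predict(x)) ** 2))
        assert plateau_fit.rss <= line_rss + 1e-9

    def test_breakpoint_stays_inside_x_range(self):
        rng = np.random.default_rng(21)
        for seed in range(20):
            x = np.sort(rng.uniform(0, 100, 15))
            y = rng.normal(0, 1, 15)
            fit = fit_linear_plateau(x, y)
            assert x.min() - 1e-9 <= fit.breakpoint <= x.max() + 1e-9

    def test_published_pairs_locate_breakpoint_near_79_5(self, trial):
        x = trial.quality_indices.loc["DEAAI"].to_numpy()
        y = trial.growth["sgr"].to_numpy()
        fit = fit_linear_plateau(x, y)
        assert fit.breakpoint == pytest.approx(79.5, abs=0.5)
        assert fit.slope > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_linear_plateau([1, 2, 3], [1, 2, 3])

    def test_zero_x_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_linear_plateau([2, 2, 2, 2], [1, 2, 3, 4])

    def test_parameter_recovery_under_noise(self):
        """Median breakpoint error over seeded replicates stays below 0.5."""
        rng = np.random.default_rng(12345)
        estimates = []
        for _ in range(50):
            x = rng.uniform(70, 90, 30)
            y = 2.46 - 0.25 * np.maximum(0.0, 79.5 - x) + rng.normal(0, 0.03, 30)
            estimates.append(fit_linear_plateau(x, y).breakpoint)
        assert abs(np.median(estimates) - 79.5) < 0.5

    def test_from_dataframe_constructor(self, trial):
        import pandas as pd

        df = pd.DataFrame(
            {"deaai": trial.quality_indices.loc["DEAAI"], "sgr": trial.growth["sgr"]}
        )
        fit = LinearPlateau.from_dataframe(df, x="deaai", y="sgr").fit()
        assert fit.breakpoint == pytest.approx(79.5, abs=0.5)

    def test_summary_mentions_parameters(self):
        x, y = _plateau_data()
        text = fit_linear_plateau(x, y).summary()
        assert "breakpoint" in text and "plateau" in text


class TestPredict:
    def test_at_breakpoint_returns_plateau(self):
        x, y = _plateau_data()
        fit = fit_linear_plateau(x, y)
        assert fit.predict([fit.breakpoint])[0] == pytest.approx(fit.plateau)

    def test_far_above_breakpoint_returns_plateau(self):
        x, y = _plateau_data()
        fit = fit_linear_plateau(x, y)
        assert fit.predict([1e6])[0] == pytest.approx(fit.plateau)

    def test_below_breakpoint_follows_rising_limb(self):
        x, y = _plateau_data()
        fit = fit_linear_plateau(x, y)
        x0 = fit.breakpoint - 3.0
        expected = fit.plateau - fit.slope * 3.0
        assert fit.predict([x0])[0] == pytest.approx(expected, rel=1e-9)

    def test_fittedvalues_match_training_x(self):
        x, y = _plateau_data()
        fit = fit_linear_plateau(x, y)
        assert np.allclose(fit.fittedvalues, fit.predict(x))


class TestQuadraticPlateau:
    def test_noiseless_self_recovery(self):
        x = np.linspace(60, 100, 15)
        y = 2.4 - 0.01 * np.maximum(0.0, 82.0 - x) ** 2
        fit = fit_quadratic_plateau(x, y)
        assert fit.breakpoint == pytest.approx(82.0, abs=1e-4)
        assert fit.rss == pytest.approx(0.0, abs=1e-10)

    def test_model_classes_share_results_interface(self):
        x, y = _plateau_data()
        for cls in (LinearPlateau, QuadraticPlateau):
            res = cls(y, x).fit()
            assert res.n == x.size
            assert set(res.params.index) == {"breakpoint", "slope", "plateau"}


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        x = np.arange(10.0)
        fit = fit_linear(x, np.full(10, 5.0))
        assert fit.slope == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(0.0)

    def test_adc_cp_predicts_growth_in_trial_tables(self, trial):
        x = trial.adc.loc["crude protein"].to_numpy()
        y = trial.growth["sgr"].to_numpy()
        fit = fit_linear(x, y)
        assert fit.slope > 0
        assert fit.p_slope < 0.05

    def test_agrees_with_statsmodels_ols(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 10, 25)
        y = 1.5 + 0.8 * x + rng.normal(0, 1, 25)
        fit = fit_linear(x, y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.intercept == pytest.approx(ols.params[0], rel=1e-9)
        assert fit.slope == pytest.approx(ols.params[1], rel=1e-9)
        assert fit.p_slope == pytest.approx(ols.pvalues[1], rel=1e-6)
        assert fit.r2 == pytest.approx(ols.rsquared, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_linear([1, 2], [1, 2])
        with pytest.raises(DegenerateInputError):
            fit_linear([1, 1, 1], [1, 2, 3])
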