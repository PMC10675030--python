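"""LAI regression (OLS + BIC subset selection) and sigmoid growth fits."""

import numpy as np
import pandas as pd
import pytest

from aeroeta.canopy import (
    LaiRegression,
    SigmoidGrowth,
    SigmoidGrowthParams,
    daily_lai_series,
    fit_sigmoid_lai,
    predict_lai,
    sigmoid,
)

TABLE_COEFFS = {"intercept": -1.071, "PH": 5.063, "VARI": 5.451, "fc": -1.661}


def _table_model() -> LaiRegression:
    model = LaiRegression()
    model.predictors_ = ("PH", "VARI", "fc")
    model.intercept_ = TABLE_COEFFS["intercept"]
    model.coef_ = np.array([TABLE_COEFFS[p] for p in model.predictors_])
    model.n_features_in_ = 3
    return model


def _synthetic_obs(n, rng, coeffs=TABLE_COEFFS, noise_sd=0.0):
    ph = rng.uniform(0.1, 1.1, n)
    vari = rng.uniform(-0.1, 0.6, n)
    fc = rng.uniform(0.0, 1.0, n)
    lai = (
        coeffs["intercept"] + coeffs["PH"] * ph + coeffs["VARI"] * vari
        + coeffs["fc"] * fc
    )
    if noise_sd:
        lai = lai + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"PH": ph, "VARI": vari, "fc": fc}), lai


class TestLaiRegression:
    def test_noise_free_coefficients_recovered_exactly(self):
        X, y = _synthetic_obs(60, np.random.default_rng(1))
        model = LaiRegression().fit(X, y)
        assert model.predictors_ == ("PH", "VARI", "fc")
        got = model.coefficients()
        for name, want in TABLE_COEFFS.items():
            assert got[name] == pytest.approx(want, rel=1e-10)
        assert model.rmse_ == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        X, y = _synthetic_obs(40, rng, noise_sd=0.4)
        model = LaiRegression(candidate_predictors=("PH",)).fit(X, y)
        design = np.column_stack([np.ones(len(y)), X["PH"]])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert model.intercept_ == pytest.approx(beta[0], rel=1e-12)
        assert model.coef_[0] == pytest.approx(beta[1], rel=1e-12)

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X, y = _synthetic_obs(50, rng, noise_sd=0.5)
        model = LaiRegression().fit(X, y)
        design = sm.add_constant(X[list(model.predictors_)])
        fit = sm.OLS(y, design).fit()
        assert model.intercept_ == pytest.approx(fit.params["const"], rel=1e-9)
        for name, coef in zip(model.predictors_, model.coef_):
            assert coef == pytest.approx(fit.params[name], rel=1e-9)

    def test_bic_selects_parsimonious_subset(self):
        # LAI depends on PH only; VARI and fc carry no signal
        rng = np.random.default_rng(11)
        n = 200
        ph = rng.uniform(0.1, 1.1, n)
        X = pd.DataFrame(
            {"PH": ph, "VARI": rng.normal(0, 0.2, n), "fc": rng.uniform(0, 1, n)}
        )
        y = 0.4 + 5.0 * ph + rng.normal(0.0, 0.3, n)
        model = LaiRegression().fit(X, y)
        assert model.predictors_ == ("PH",)

    def test_selected_bic_is_minimum_over_exhaustive_enumeration(self):
        import itertools

        rng = np.random.default_rng(23)
        X, y = _synthetic_obs(80, rng, noise_sd=0.5)
        model = LaiRegression().fit(X, y)
        # independent enumeration of all 7 subsets
        best = np.inf
        n = len(y)
        for r in range(1, 4):
            for subset in itertools.combinations(("PH", "VARI", "fc"), r):
                design = np.column_stack(
                    [np.ones(n)] + [X[c].to_numpy() for c in subset]
                )
                beta = np.linalg.solve(design.T @ design, design.T @ y)
                rss = float(((y - design @ beta) ** 2).sum())
                k = len(subset) + 1
                best = min(best, n * np.log(rss / n) + k * np.log(n))
        assert model.bic_ == pytest.approx(best, rel=1e-12)

    def test_too_few_observations_rejected(self):
        X, y = _synthetic_obs(3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            LaiRegression().fit(X, y)

    @pytest.mark.parametrize(
        "ph, vari, fc, expected",
        [
            (0.0, 0.0, 0.0, -1.071),
            (0.5, 0.3, 0.5, 5.063 * 0.5 + 5.451 * 0.3 - 1.661 * 0.5 - 1.071),
        ],
    )
    def test_prediction_is_the_linear_combination(self, ph, vari, fc, expected):
        assert predict_lai(_table_model(), ph, vari, fc) == pytest.approx(expected)

    def test_zero_coefficient_model_predicts_zero(self):
        model = _table_model()
        model.coef_ = np.zeros(3)
        model.intercept_ = 0.0
        assert predict_lai(model, 0.9, 0.4, 0.7) == 0.0

    def test_floor_at_zero_option(self):
        model = _table_model()
        model.floor_at_zero = True
        assert predict_lai(model, 0.0, 0.0, 0.0) == 0.0


class TestSigmoidGrowth:
    TRUTH = SigmoidGrowthParams(a=0.10, b=120.0, c=6.0)

    def test_half_maximum_at_midpoint(self):
        assert sigmoid(self.TRUTH.b, 0.1, self.TRUTH.b, 6.0) == pytest.approx(3.0)

    def test_noise_free_parameter_recovery(self):
        das = np.arange(60, 181, 10)
        lai = sigmoid(das, self.TRUTH.a, self.TRUTH.b, self.TRUTH.c)
        fit = SigmoidGrowth().fit(das, lai)
        assert fit.a_ == pytest.approx(self.TRUTH.a, rel=1e-6)
        assert fit.b_ == pytest.approx(self.TRUTH.b, rel=1e-6)
        assert fit.c_ == pytest.approx(self.TRUTH.c, rel=1e-6)

    def test_seed_insensitive_with_deterministic_start(self):
        das = np.arange(60, 181, 10)
        rng = np.random.default_rng(4)
        lai = sigmoid(das, 0.11, 118.0, 5.5) + rng.normal(0, 0.2, das.size)
        a = SigmoidGrowth(random_state=0).fit(das, lai)
        b = SigmoidGrowth(random_state=99).fit(das, lai)
        assert (a.a_, a.b_, a.c_) == (b.a_, b.b_, b.c_)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            SigmoidGrowth().fit([100, 120, 140], [1.0, 3.0, 5.0])

    def test_curve_approaches_asymptote(self):
        params = fit_sigmoid_lai(
            np.arange(60, 181, 10),
            sigmoid(np.arange(60, 181, 10), 0.1, 120.0, 6.0),
        )
        assert sigmoid(1e6, params.a, params.b, params.c) == pytest.approx(
            params.c
        )


class TestDailySeries:
    PARAMS = SigmoidGrowthParams(a=0.1, b=120.0, c=6.0)

    def test_length_and_midpoint_value(self):
        series = daily_lai_series(self.PARAMS, 165)
        assert len(series) == 166
        assert series[120] == pytest.approx(3.0, rel=1e-9)

    def test_monotone_for_positive_slope(self):
        series = daily_lai_series(self.PARAMS, 165)
        assert (np.diff(series) > 0).all()

    def test_invalid_maturity_rejected(self):
        with pytest.raises(ValueError):
            daily_lai_series(self.PARAMS, 0)
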