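"""Leaf-area-index models: multiple regression on UAV observables and the
seasonal sigmoid growth curve.

``LaiRegression`` maps per-plot plant height (PH, m), the VARI greenness
index and fractional cover (fc) to LAI with an ordinary-least-squares
multiple regression; the predictor subset is chosen by exhaustive search
over all non-empty subsets using the Bayesian information criterion,
BIC = n·ln(RSS/n) + k·ln(n) with k counting the intercept.

``SigmoidGrowth`` fits the logistic seasonal trajectory
LAI(DAS) = c / (1 + exp(−a·(DAS − b))) — a the slope, b the midpoint in
days after sowing, c the asymptote — by nonlinear least squares with a
deterministic initialisation and bounded seeded restarts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LaiRegression",
    "SigmoidGrowth",
    "SigmoidGrowthParams",
    "SigmoidFitError",
    "fit_lai_regression",
    "predict_lai",
    "fit_sigmoid_lai",
    "daily_lai_series",
    "sigmoid",
    "CANDIDATE_PREDICTORS",
]

CANDIDATE_PREDICTORS = ("PH", "VARI", "fc")


class SigmoidFitError(RuntimeError):
    """Sigmoid fit failed to converge after bounded restarts."""


def _as_frame(X, columns) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(columns):
        raise ValueError(
            f"expected a table with columns {columns}; got shape {X.shape}"
        )
    return pd.DataFrame(X, columns=list(columns))


class LaiRegression(RegressorMixin, BaseEstimator):
    """OLS regression of LAI on {PH, VARI, fc} with BIC subset selection.

    Parameters
    ----------
    candidate_predictors : tuple of str
        Column names searched over; every non-empty subset is fit and the
        one with the lowest BIC is kept.
    floor_at_zero : bool
        Floor predictions at 0 (off by default: raw linear predictions are
        kept for model transparency, the line can go negative for sparse
        canopies).

    Attributes
    ----------
    predictors_ : tuple of str — selected subset
    coef_ : ndarray — coefficients in ``predictors_`` order
    intercept_ : float
    r2_, rmse_, bic_, n_obs_ : fit statistics on the calibration set
    """

    def __init__(
        self,
        candidate_predictors: tuple[str, ...] = CANDIDATE_PREDICTORS,
        floor_at_zero: bool = False,
    ):
        self.candidate_predictors = candidate_predictors
        self.floor_at_zero = floor_at_zero

    def fit(self, X, y):
        frame = _as_frame(X, self.candidate_predictors)
        missing = [c for c in self.candidate_predictors if c not in frame.columns]
        if missing:
            raise ValueError(f"missing predictor columns: {missing}")
        if not self.candidate_predictors:
            raise ValueError("need at least one candidate predictor")
        y = np.asarray(y, dtype=float)
        n = len(y)
        if n < 8:
            raise ValueError(f"need >= 8 complete observations, got {n}")
        if n <= len(self.candidate_predictors) + 1:
            raise ValueError("more coefficients than observations")

        best = None
        for r in range(1, len(self.candidate_predictors) + 1):
            for subset in itertools.combinations(self.candidate_predictors, r):
                design = np.column_stack(
                    [np.ones(n)] + [frame[c].to_numpy(dtype=float) for c in subset]
                )
                if np.linalg.matrix_rank(design) < design.shape[1]:
                    raise ValueError(f"rank-deficient design for subset {subset}")
                beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
                resid = y - design @ beta
                rss = float(resid @ resid)
                k = design.shape[1]
                # guard the log for perfect fits
                bic = n * math.log(max(rss, 1e-300) / n) + k * math.log(n)
                if best is None or bic < best[0]:
                    best = (bic, subset, beta, rss)

        bic, subset, beta, rss = best
        self.predictors_ = subset
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.n_obs_ = n
        self.bic_ = float(bic)
        self.rmse_ = math.sqrt(rss / n)
        tss = float(((y - y.mean()) ** 2).sum())
        self.r2_ = 1.0 - rss / tss if tss > 0 else 1.0
        self.n_features_in_ = len(self.candidate_predictors)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        frame = _as_frame(X, self.candidate_predictors)
        missing = [c for c in self.predictors_ if c not in frame.columns]
        if missing:
            raise ValueError(f"model requires predictors {missing}")
        vals = self.intercept_ + sum(
            coef * frame[name].to_numpy(dtype=float)
            for coef, name in zip(self.coef_, self.predictors_)
        )
        vals = np.asarray(vals, dtype=float)
        if self.floor_at_zero:
            vals = np.maximum(vals, 0.0)
        return vals

    def coefficients(self) -> dict[str, float]:
        """Mapping {intercept, predictor: coefficient} of the fitted line."""
        check_is_fitted(self, "coef_")
        out = {"intercept": self.intercept_}
        out.update(dict(zip(self.predictors_, map(float, self.coef_))))
        return out


def fit_lai_regression(
    observations: pd.DataFrame,
    candidate_predictors: tuple[str, ...] = CANDIDATE_PREDICTORS,
    lai_column: str = "LAI",
) -> LaiRegression:
    """Fit the LAI regression from a table holding predictors and measured LAI."""
    obs = observations.dropna(subset=[lai_column, *candidate_predictors])
    model = LaiRegression(candidate_predictors=candidate_predictors)
    return model.fit(obs[list(candidate_predictors)], obs[lai_column].to_numpy())


def predict_lai(model: LaiRegression, ph, vari, fc):
    """Evaluate a fitted LAI regression at (PH, VARI, fc)."""
    frame = pd.DataFrame(
        {
            "PH": np.atleast_1d(np.asarray(ph, dtype=float)),
            "VARI": np.atleast_1d(np.asarray(vari, dtype=float)),
            "fc": np.atleast_1d(np.asarray(fc, dtype=float)),
        }
    )
    out = model.predict(frame)
    return float(out[0]) if np.ndim(ph) == 0 and out.size == 1 else out


# ---------------------------------------------------------------------------
# sigmoid seasonal trajectory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SigmoidGrowthParams:
    """Logistic growth parameters: slope a (day⁻¹), midpoint b (DAS),
    asymptote c (LAI units)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("asymptote c must be positive")


def sigmoid(das, a: float, b: float, c: float):
    das = np.asarray(das, dtype=float)
    out = c / (1.0 + np.exp(-a * (das - b)))
    return float(out) if out.ndim == 0 else out


def _initial_guess(das: np.ndarray, lai: np.ndarray) -> tuple[float, float, float]:
    c0 = float(lai.max())
    order = np.argsort(das)
    d, v = das[order], lai[order]

    def das_at(level: float) -> float:
        target = level * c0
        idx = np.searchsorted(v, target)
        if idx <= 0:
            return float(d[0])
        if idx >= len(d):
            return float(d[-1])
        lo, hi = v[idx - 1], v[idx]
        if hi == lo:
            return float(d[idx])
        w = (target - lo) / (hi - lo)
        return float(d[idx - 1] + w * (d[idx] - d[idx - 1]))

    b0 = das_at(0.5)
    rise = max(das_at(0.8) - das_at(0.2), 1.0)
    a0 = 4.0 / rise
    return a0, b0, c0


class SigmoidGrowth(RegressorMixin, BaseEstimator):
    """Logistic LAI(DAS) trajectory fitted by nonlinear least squares.

    Deterministic initialisation (asymptote from the maximum, midpoint by
    linear interpolation at half-maximum, slope from the 20–80% rise
    span); if the optimiser fails, up to ``n_restarts`` perturbed starts
    drawn from a seeded generator are tried before raising
    :class:`SigmoidFitError`.
    """

    def __init__(self, n_restarts: int = 8, random_state: int = 0,
                 max_nfev: int = 10000):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.max_nfev = max_nfev

    def fit(self, das, lai):
        das = np.asarray(das, dtype=float).ravel()
        lai = np.asarray(lai, dtype=float).ravel()
        if das.size != lai.size:
            raise ValueError("DAS and LAI lengths differ")
        if das.size < 4:
            raise ValueError("need >= 4 observations to fit a sigmoid")
        p0 = _initial_guess(das, lai)
        rng = np.random.default_rng(self.random_state)
        bounds = ([1e-4, das.min() - 200.0, 1e-6],
                  [2.0, das.max() + 200.0, 50.0])
        last_err: Exception | None = None
        for attempt in range(self.n_restarts + 1):
            start = p0 if attempt == 0 else (
                p0[0] * rng.uniform(0.5, 2.0),
                p0[1] + rng.uniform(-15.0, 15.0),
                p0[2] * rng.uniform(0.8, 1.25),
            )
            start = tuple(np.clip(start, bounds[0], bounds[1]))
            try:
                popt, pcov = curve_fit(
                    sigmoid, das, lai, p0=start, bounds=bounds,
                    max_nfev=self.max_nfev,
                )
            except RuntimeError as err:  # pragma: no cover - rare
                last_err = err
                continue
            self.a_, self.b_, self.c_ = map(float, popt)
            resid = lai - sigmoid(das, *popt)
            self.rmse_ = float(np.sqrt(np.mean(resid ** 2)))
            self.n_obs_ = int(das.size)
            self.n_restarts_used_ = attempt
            return self
        raise SigmoidFitError(
            f"sigmoid fit did not converge after {self.n_restarts + 1} starts: "
            f"{last_err}"
        )

    def predict(self, das):
        check_is_fitted(self, "c_")
        return sigmoid(np.asarray(das, dtype=float), self.a_, self.b_, self.c_)

    @property
    def params_(self) -> SigmoidGrowthParams:
        check_is_fitted(self, "c_")
        return SigmoidGrowthParams(self.a_, self.b_, self.c_)


def fit_sigmoid_lai(das, lai, **kwargs) -> SigmoidGrowthParams:
    """Fit the seasonal sigmoid and return its parameters."""
    return SigmoidGrowth(**kwargs).fit(das, lai).params_


def daily_lai_series(
    params: SigmoidGrowthParams, maturity_das: int
) -> np.ndarray:
    """LAI at every integer DAS in [0, maturity_das] (length maturity+1)."""
    if maturity_das < 1:
        raise ValueError("maturity must be >= 1 DAS")
    das = np.arange(0, int(maturity_das) + 1)
    return sigmoid(das, params.a, params.b, params.c)
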