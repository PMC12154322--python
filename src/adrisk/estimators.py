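"""Scikit-learn-style estimators wrapping the fit/predict-shaped pieces.

Three estimators cover the learnable parts of the framework and compose
with sklearn pipelines and model selection:

* :class:`ExponentialTrajectoryRegressor` — fits one biomarker's
  k*exp(-m*age) trajectory by log-linear least squares.
* :class:`CognitiveImpairmentScorer` — calibrates the CI model's
  (alpha, beta, w_i) against target scores by profiled ridge regression
  and predicts observation-based CI for new instances.
* :class:`RiskZoneClassifier` — maps (age, CI) pairs to Safe / Mild Risk /
  Unsafe labels under an age-band registry (no free parameters; ``fit``
  only validates and records classes).

Inputs may be DataFrames with canonical columns or plain arrays in
canonical column order.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import AGE_COLUMN, BIOMARKERS, CI_COLUMN, COLUMNS, CohortTable
from .ci import CIParams, calibrate_ci_params, fit_trajectory_params, score_cohort
from .zones import AgeBand, classify_ci

__all__ = [
    "ExponentialTrajectoryRegressor",
    "CognitiveImpairmentScorer",
    "RiskZoneClassifier",
]


def _as_cohort(X) -> CohortTable:
    if isinstance(X, CohortTable):
        return X
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(COLUMNS):
            raise ValueError(
                f"expected shape (n, {len(COLUMNS)}) in canonical column order, "
                f"got {arr.shape}"
            )
        df = pd.DataFrame(arr, columns=list(COLUMNS))
    return CohortTable(df=df)


class ExponentialTrajectoryRegressor(RegressorMixin, BaseEstimator):
    """Fit value = k * exp(-m * age) by least squares on the log scale.

    Attributes
    ----------
    k_ : float
        Amplitude at age 0.
    m_ : float
        Decay rate (negative for rising trajectories).
    rmse_ : float
        Root-mean-square error on the original scale.
    """

    def fit(self, X, y):
        ages = np.asarray(X, dtype=float).reshape(-1)
        fit = fit_trajectory_params(ages, np.asarray(y, dtype=float))
        self.k_ = fit["k"]
        self.m_ = fit["m"]
        self.rmse_ = fit["rmse"]
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "k_")
        ages = np.asarray(X, dtype=float).reshape(-1)
        return self.k_ * np.exp(-self.m_ * ages)


class CognitiveImpairmentScorer(RegressorMixin, BaseEstimator):
    """Calibrate the CI model against target scores and predict CI.

    Parameters
    ----------
    ridge : float
        L2 penalty on the (scaled) linear coefficients; keeps the
        under-determined calibration well-posed.
    beta_grid : sequence of float, optional
        Candidate age-rate values profiled during the fit (default
        0 to 0.1 in steps of 0.001).

    After ``fit``, ``params_`` holds the calibrated :class:`CIParams` and
    ``predict`` evaluates the observation-based CI score.
    """

    def __init__(self, ridge: float = 1e-3, beta_grid: Optional[Sequence[float]] = None):
        self.ridge = ridge
        self.beta_grid = beta_grid

    def fit(self, X, y):
        cohort = _as_cohort(X)
        self.params_ = calibrate_ci_params(
            cohort, np.asarray(y, dtype=float), ridge=self.ridge, beta_grid=self.beta_grid
        )
        self.n_features_in_ = len(COLUMNS)
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        return score_cohort(_as_cohort(X), self.params_)


class RiskZoneClassifier(ClassifierMixin, BaseEstimator):
    """Classify (age, CI) pairs into risk zones under an age-band registry.

    Parameters
    ----------
    registry : sequence of AgeBand, optional
        Band registry; the package default (bands 30-70) when None.

    ``X`` may be a DataFrame with ``Age`` and ``CI`` columns or an array of
    shape (n, 2) ordered (age, ci).  The classifier has no parameters to
    learn; ``fit`` validates the registry and sets ``classes_``.
    """

    def __init__(self, registry: Optional[Sequence[AgeBand]] = None):
        self.registry = registry

    def fit(self, X=None, y=None):
        self.classes_ = np.array(["Safe", "Mild Risk", "Unsafe"], dtype=object)
        self.n_features_in_ = 2
        return self

    def _pairs(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[[AGE_COLUMN, CI_COLUMN]].to_numpy(dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"expected shape (n, 2) of (age, ci), got {arr.shape}")
        return arr

    def predict(self, X):
        check_is_fitted(self, "classes_")
        pairs = self._pairs(X)
        return np.array(
            [classify_ci(a, c, self.registry).value for a, c in pairs], dtype=object
        )
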