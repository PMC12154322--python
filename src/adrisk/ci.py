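"""Cognitive-impairment (CI) scoring.

The CI score combines an exponential age term with a weighted sum of four
biomarker contributions:

    CI(A) = alpha * exp(beta * A) + sum_i w_i * k_i * exp(-m_i * A)

where A is age, ``alpha``/``beta`` scale the accelerating age component and
each biomarker i has a weight ``w_i``, amplitude ``k_i`` and rate ``m_i``.
The exponential terms are written uniformly as k*exp(-m*A); biomarkers that
rise with age (amyloid PET, CSF Tau, the MRI/FDG-PET composite) simply take
``m < 0``, and the protective direction of CSF A-beta-42 is encoded as
``w_1 < 0`` so that higher measured A-beta-42 lowers the score.

Two evaluation forms are provided: the model-based form above (a pure
function of age) and an observation form in which each modeled term
k_i*exp(-m_i*A) is replaced by the individual's measured biomarker value —
linear in each measurement at fixed age, and identical to the model form
when measurements sit exactly on their modeled trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .cohort import AGE_COLUMN, BIOMARKERS, BiomarkerRecord, CohortTable

__all__ = [
    "TermParams",
    "CIParams",
    "biomarker_term",
    "ci_from_age",
    "ci_from_observation",
    "score_cohort",
    "fit_trajectory_params",
    "calibrate_ci_params",
]

ArrayLike = Union[float, Sequence[float], np.ndarray]


@dataclass(frozen=True)
class TermParams:
    """One biomarker's (w, k, m): weight, amplitude, rate."""

    w: float
    k: float
    m: float

    def __post_init__(self) -> None:
        for name in ("w", "k", "m"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class CIParams:
    """Parameters of the CI score.

    ``terms`` is an ordered four-tuple for (CSF_Ab42, Amyloid_PET, CSF_Tau,
    MRI_FDG_PET) in that fixed canonical order.
    """

    alpha: float
    beta: float
    terms: tuple[TermParams, TermParams, TermParams, TermParams]

    def __post_init__(self) -> None:
        if not (self.alpha >= 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha!r}")
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if len(self.terms) != len(BIOMARKERS):
            raise ValueError(f"need {len(BIOMARKERS)} terms, got {len(self.terms)}")
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def weights(self) -> np.ndarray:
        return np.array([t.w for t in self.terms])

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "terms": {
                name: {"w": t.w, "k": t.k, "m": t.m}
                for name, t in zip(BIOMARKERS, self.terms)
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CIParams":
        terms = tuple(
            TermParams(**{k: float(v) for k, v in d["terms"][name].items()})
            for name in BIOMARKERS
        )
        return cls(alpha=float(d["alpha"]), beta=float(d["beta"]), terms=terms)


def biomarker_term(age: ArrayLike, k: float, m: float) -> Union[float, np.ndarray]:
    """Modeled biomarker level k * exp(-m * age)."""
    age_arr = np.asarray(age, dtype=float)
    val = k * np.exp(-m * age_arr)
    return float(val) if age_arr.ndim == 0 else val


def ci_from_age(age: ArrayLike, params: CIParams) -> Union[float, np.ndarray]:
    """Model-based CI score at a given age (no measurements needed)."""
    age_arr = np.asarray(age, dtype=float)
    val = params.alpha * np.exp(params.beta * age_arr)
    for t in params.terms:
        val = val + t.w * biomarker_term(age_arr, t.k, t.m)
    return float(val) if age_arr.ndim == 0 else val


def ci_from_observation(record: BiomarkerRecord, params: CIParams) -> float:
    """Observation-based CI score: measured values replace the modeled terms.

    Linear in each biomarker at fixed age; reduces to :func:`ci_from_age`
    when all weights are zero or when every measurement equals its modeled
    trajectory value.
    """
    val = params.alpha * math.exp(params.beta * record.age)
    for t, v in zip(params.terms, record.values):
        val += t.w * v
    return val


def score_cohort(cohort: CohortTable, params: CIParams) -> np.ndarray:
    """Vectorized observation-based CI over a cohort frame."""
    df = cohort.df
    ages = df[AGE_COLUMN].to_numpy(dtype=float)
    val = params.alpha * np.exp(params.beta * ages)
    for t, name in zip(params.terms, BIOMARKERS):
        val = val + t.w * df[name].to_numpy(dtype=float)
    return val


def fit_trajectory_params(
    ages: Sequence[float], values: Sequence[float]
) -> dict[str, float]:
    """Fit k * exp(-m * age) to data by log-linear least squares.

    Regresses log(value) on age, so values must be strictly positive and
    at least two distinct ages are required.  Returns the back-transformed
    ``k`` and ``m`` plus the RMSE on the original scale.
    """
    ages_arr = np.asarray(ages, dtype=float)
    vals = np.asarray(values, dtype=float)
    if ages_arr.size != vals.size:
        raise ValueError("ages and values must have equal length")
    if ages_arr.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(vals <= 0):
        raise ValueError("all values must be > 0 for a log-linear fit")
    if np.ptp(ages_arr) == 0:
        raise ValueError("degenerate input: all ages identical")
    res = stats.linregress(ages_arr, np.log(vals))
    k = float(np.exp(res.intercept))
    m = float(-res.slope)
    pred = k * np.exp(-m * ages_arr)
    rmse = float(np.sqrt(np.mean((pred - vals) ** 2)))
    return {"k": k, "m": m, "rmse": rmse}


_BETA_GRID = np.round(np.arange(0.0, 0.1 + 1e-9, 0.001), 6)


def _ridge_solve(X: np.ndarray, y: np.ndarray, ridge: float):
    """Scaled ridge solve; returns (coef, penalized_loss).

    Columns are scaled to unit root-mean-square before penalization so the
    penalty treats biomarkers with very different numeric ranges evenly;
    coefficients are returned on the original scale.  With ridge = 0 a
    singular design raises ``numpy.linalg.LinAlgError``.
    """
    scales = np.sqrt(np.mean(X**2, axis=0))
    scales[scales == 0] = 1.0
    Xs = X / scales
    A = Xs.T @ Xs + ridge * np.eye(X.shape[1])
    theta_s = np.linalg.solve(A, Xs.T @ y)
    resid = y - Xs @ theta_s
    loss = float(resid @ resid + ridge * (theta_s @ theta_s))
    return theta_s / scales, loss


def calibrate_ci_params(
    cohort: CohortTable,
    target_ci: Sequence[float],
    ridge: float = 1e-3,
    beta_grid: Optional[Sequence[float]] = None,
) -> CIParams:
    """Calibrate (alpha, beta, w_i) so observation scores match targets.

    beta is profiled over a fixed grid (default 0 to 0.1, step 0.001); at
    each beta the remaining coefficients solve a ridge-penalized linear
    least-squares problem in the design [exp(beta*A), B_1..B_4].  The fit
    is deterministic and invariant to record order.  A negative fitted
    alpha is resolved by refitting with the age column removed (alpha=0),
    honoring the constraint alpha >= 0.

    Each biomarker's (k_i, m_i) is recovered from its own age trajectory in
    the cohort via :func:`fit_trajectory_params` where possible (positive
    values, >= 2 distinct ages), else falls back to a constant term at the
    cohort mean, so the model-based form mirrors the calibration cohort.
    """
    df = cohort.df
    y = np.asarray(target_ci, dtype=float)
    if len(df) != y.size or y.size < 1:
        raise ValueError("target_ci must match the cohort length (>= 1)")
    ages = df[AGE_COLUMN].to_numpy(dtype=float)
    B = df[list(BIOMARKERS)].to_numpy(dtype=float)
    grid = _BETA_GRID if beta_grid is None else np.asarray(beta_grid, dtype=float)

    best: Optional[tuple[float, float, np.ndarray]] = None  # (loss, beta, coef)
    for beta in grid:
        X = np.column_stack([np.exp(beta * ages), B])
        coef, loss = _ridge_solve(X, y, ridge)
        if best is None or loss < best[0] - 1e-15:
            best = (loss, float(beta), coef)
    assert best is not None
    _, beta, coef = best
    alpha, w = float(coef[0]), coef[1:]
    if alpha < 0:
        # drop the age column and refit at the same beta
        coef_w, _ = _ridge_solve(B, y, ridge)
        alpha, w = 0.0, coef_w

    terms = []
    for j, name in enumerate(BIOMARKERS):
        vals = B[:, j]
        try:
            fit = fit_trajectory_params(ages, vals)
            k, m = fit["k"], fit["m"]
        except ValueError:
            k, m = float(np.mean(vals)), 0.0
        terms.append(TermParams(w=float(w[j]), k=k, m=m))
    return CIParams(alpha=alpha, beta=beta, terms=tuple(terms))
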