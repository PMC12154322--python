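"""Sigmoid biomarker trajectories and the synthetic cohort generator.

Pathological change in preclinical Alzheimer's disease starts subtly,
accelerates through midlife and plateaus late — a shape captured here by a
logistic curve

    S(x) = L / (1 + exp(k * (x - x0)))

where ``L`` is the plateau (maximum potential value of the biomarker),
``k`` a scaling rate and ``x0`` the reference point.  Note the sign
convention: as written the curve is *decreasing* in ``x`` for ``k > 0``;
rising trajectories (amyloid PET, CSF Tau, FDG-PET composites) therefore
use ``k < 0``.  When simulating trajectories ``x`` is interpreted as age.

The module also provides the seeded synthetic cohort generator used in
place of unavailable source data, descriptive per-age-bin summaries, and
simple biomarker-vs-biomarker regression (the classic inverse relationship
between CSF A-beta-42 and CSF Tau).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AGE_COLUMN, BIOMARKERS, COLUMNS, SYNTHETIC_COLUMN, CohortTable

__all__ = [
    "SigmoidParams",
    "NoiseSpec",
    "RegressionSummary",
    "sigmoid",
    "sigmoid_derivative",
    "simulate_trajectory",
    "generate_cohort",
    "descriptive_summary",
    "correlate",
]

# exp() overflows double precision beyond ~709.78
_EXP_CLIP = 709.0

ArrayLike = Union[float, Sequence[float], np.ndarray]


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters (L, k, x0) of one biomarker's logistic age trajectory."""

    L: float
    k: float
    x0: float

    def __post_init__(self) -> None:
        if not (self.L > 0 and math.isfinite(self.L)):
            raise ValueError(f"L must be positive and finite, got {self.L!r}")
        if not (math.isfinite(self.k) and math.isfinite(self.x0)):
            raise ValueError("k and x0 must be finite")


_NOISE_KINDS = {
    "none": "none",
    "additive-gaussian": "additive-gaussian",
    "additive": "additive-gaussian",
    "multiplicative-gaussian": "multiplicative-gaussian",
    "multiplicative": "multiplicative-gaussian",
}


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for simulated trajectories.

    ``additive-gaussian`` adds N(0, scale) in biomarker units;
    ``multiplicative-gaussian`` multiplies by (1 + N(0, scale)).
    Simulated values are floored at zero either way.
    """

    kind: str = "none"
    scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        object.__setattr__(self, "kind", _NOISE_KINDS[self.kind])
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")


@dataclass(frozen=True)
class RegressionSummary:
    """OLS slope/intercept of y on x plus the Pearson correlation."""

    slope: float
    intercept: float
    r: float
    n: int


def sigmoid(x: ArrayLike, params: SigmoidParams) -> Union[float, np.ndarray]:
    """Evaluate S(x) = L / (1 + exp(k (x - x0))).

    Strictly within (0, L) for finite arguments; where the exponent would
    overflow the appropriate asymptote (0 or L) is returned exactly.
    """
    x_arr = np.asarray(x, dtype=float)
    u = params.k * (x_arr - params.x0)
    u_safe = np.clip(u, -_EXP_CLIP, _EXP_CLIP)
    val = params.L / (1.0 + np.exp(u_safe))
    val = np.where(u > _EXP_CLIP, 0.0, val)
    val = np.where(u < -_EXP_CLIP, params.L, val)
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(val)
    return val


def sigmoid_derivative(x: ArrayLike, params: SigmoidParams) -> Union[float, np.ndarray]:
    """Closed-form derivative S'(x) = -k * S(x) * (1 - S(x)/L).

    Negative where the curve falls (k > 0), positive where it rises, and
    exactly zero at the clamped asymptotes and for k = 0.
    """
    s = np.asarray(sigmoid(x, params), dtype=float)
    val = -params.k * s * (1.0 - s / params.L)
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return float(val)
    return val


def _apply_noise(
    base: np.ndarray, noise: Optional[NoiseSpec], rng: Optional[np.random.Generator]
) -> np.ndarray:
    if noise is None or noise.kind == "none" or noise.scale == 0.0:
        return np.maximum(base, 0.0)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, noise.scale, size=base.shape)
    if noise.kind == "additive-gaussian":
        out = base + eps
    else:  # multiplicative-gaussian
        out = base * (1.0 + eps)
    return np.maximum(out, 0.0)


def simulate_trajectory(
    ages: ArrayLike,
    params: SigmoidParams,
    noise: Optional[NoiseSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sigmoid values at each age, perturbed per the noise spec.

    With ``noise=None`` (or kind ``none``) the output equals ``sigmoid(age)``
    exactly.  An explicit ``rng`` overrides the seed in ``noise`` so callers
    can route several trajectories through one seeded stream.
    """
    ages_arr = np.atleast_1d(np.asarray(ages, dtype=float))
    if ages_arr.size == 0:
        raise ValueError("ages must be non-empty")
    base = np.asarray(sigmoid(ages_arr, params), dtype=float)
    return _apply_noise(base, noise, rng)


def generate_cohort(
    n_per_age: int,
    age_range: tuple[float, float],
    params: Mapping[str, SigmoidParams],
    noise: Optional[NoiseSpec] = None,
    tau_coupling: float = -0.5,
    noise_scales: Optional[Mapping[str, float]] = None,
) -> CohortTable:
    """Generate a synthetic cross-sectional cohort on an integer age grid.

    ``n_per_age`` instances are drawn at every integer age in the closed
    interval ``age_range``.  Each biomarker follows its own sigmoid
    trajectory with independent noise; CSF Tau additionally receives
    ``tau_coupling * (Ab42_value - Ab42_curve)`` so that, with
    ``tau_coupling < 0``, individuals whose A-beta-42 falls below their
    age trajectory show correspondingly elevated Tau — the inverse
    amyloid/Tau relationship seen in amyloid-driven neurodegeneration.

    Randomness is driven by ``noise.seed`` through one child stream per
    biomarker (fixed canonical order), so results do not depend on the
    mapping's iteration order and are bit-reproducible for a given seed.
    """
    missing = [b for b in BIOMARKERS if b not in params]
    if missing:
        raise KeyError(f"missing sigmoid params for {missing}")
    lo, hi = float(age_range[0]), float(age_range[1])
    if hi < lo:
        raise ValueError(f"empty age range {age_range!r}")
    if n_per_age < 1:
        raise ValueError("n_per_age must be >= 1")
    ages = np.repeat(np.arange(math.ceil(lo), math.floor(hi) + 1, dtype=float), n_per_age)
    if ages.size == 0:
        raise ValueError(f"age range {age_range!r} contains no integer age")

    seed = noise.seed if noise is not None else 0
    children = np.random.SeedSequence(seed).spawn(len(BIOMARKERS))
    cols: dict[str, np.ndarray] = {AGE_COLUMN: ages}
    for child, name in zip(children, BIOMARKERS):
        spec = noise
        if noise is not None and noise_scales is not None and name in noise_scales:
            spec = NoiseSpec(noise.kind, float(noise_scales[name]), noise.seed)
        cols[name] = simulate_trajectory(
            ages, params[name], spec, rng=np.random.default_rng(child)
        )
    ab42_curve = np.asarray(sigmoid(ages, params["CSF_Ab42"]), dtype=float)
    cols["CSF_Tau"] = np.maximum(
        cols["CSF_Tau"] + tau_coupling * (cols["CSF_Ab42"] - ab42_curve), 0.0
    )
    df = pd.DataFrame(cols, columns=list(COLUMNS))
    df[SYNTHETIC_COLUMN] = True
    return CohortTable(df=df, provenance=f"generated(seed={seed})")


def descriptive_summary(cohort: CohortTable, bin_width: float) -> pd.DataFrame:
    """Per-age-bin, per-biomarker descriptive moments.

    Ages are binned as [10, 10+w), [10+w, 10+2w), ...; empty bins are
    omitted.  Returns a tidy frame with columns ``bin_left``, ``bin_right``,
    ``biomarker``, ``n``, ``mean``, ``sd``, ``min``, ``max``.  The standard
    deviation is the population form (ddof=0) so a single-record bin
    reports sd 0 rather than an undefined value.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    df = cohort.df
    rows = []
    if len(df):
        idx = np.floor((df[AGE_COLUMN].to_numpy(dtype=float) - 10.0) / bin_width).astype(int)
        for b in sorted(set(idx)):
            sub = df.loc[idx == b]
            for name in BIOMARKERS:
                vals = sub[name].dropna().to_numpy(dtype=float)
                if vals.size == 0:
                    continue
                rows.append(
                    {
                        "bin_left": 10.0 + b * bin_width,
                        "bin_right": 10.0 + (b + 1) * bin_width,
                        "biomarker": name,
                        "n": int(vals.size),
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=0)),
                        "min": float(vals.min()),
                        "max": float(vals.max()),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["bin_left", "bin_right", "biomarker", "n", "mean", "sd", "min", "max"],
    )


def correlate(cohort: CohortTable, x_col: str, y_col: str) -> RegressionSummary:
    """OLS regression of ``y_col`` on ``x_col`` plus Pearson r.

    Requires at least two complete pairs and non-degenerate x.
    """
    df = cohort.df
    for c in (x_col, y_col):
        if c not in df.columns:
            raise KeyError(f"unknown column {c!r}")
    pairs = df[[x_col, y_col]].dropna()
    n = len(pairs)
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs, got {n}")
    x = pairs[x_col].to_numpy(dtype=float)
    y = pairs[y_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"zero variance in {x_col!r}")
    res = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=n,
    )
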