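"""Age-banded risk-zone classification and threshold flagging.

A registry of age bands supplies two CI cut-points per band: gamma
(Safe/Mild boundary) and delta (Mild/Unsafe boundary).  Classification is

    Safe       CI <= gamma
    Mild Risk  gamma < CI <= delta
    Unsafe     CI > delta

with bands keyed on the half-open convention (lower, upper], so an age on
a band's upper edge belongs to that band.  Younger bands carry stricter
cuts — the default registry uses (gamma, delta) = (3, 6), (4, 7), (5, 8),
(6, 9) for 30-40, 40-50, 50-60 and 60-70 — preventing overestimation of
risk in the young and underestimation in the old.

Independent of the CI bands, per-age-group threshold tables flag each
individual biomarker as Normal / Low Risk / High Risk.  CSF A-beta-42 runs
opposite to the other markers (lower values are riskier), encoded by a
per-biomarker direction flag.

The module also answers two planning questions on a modeled CI trajectory:
which value of one biomarker keeps an individual Safe given the other
three (``safe_biomarker_bounds``), and between which ages a trajectory
leaves the Safe zone and enters the Unsafe zone (``intervention_window``).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import AGE_COLUMN, BIOMARKERS, CI_COLUMN, BiomarkerRecord, CohortTable
from .ci import CIParams, ci_from_age, ci_from_observation, score_cohort

__all__ = [
    "ZoneLabel",
    "FlagLabel",
    "AgeBand",
    "ThresholdTable",
    "RiskAssessment",
    "ScreenResult",
    "InterventionWindow",
    "band_for_age",
    "classify_ci",
    "classify_instance",
    "four_zone_label",
    "flag_biomarker",
    "screen_cohort",
    "safe_biomarker_bounds",
    "intervention_window",
]

logger = logging.getLogger(__name__)


class ZoneLabel(str, enum.Enum):
    """Three-zone CI classification label."""

    SAFE = "Safe"
    MILD_RISK = "Mild Risk"
    UNSAFE = "Unsafe"

    @property
    def rank(self) -> int:
        return {"Safe": 0, "Mild Risk": 1, "Unsafe": 2}[self.value]


class FlagLabel(str, enum.Enum):
    """Single-biomarker threshold flag."""

    NORMAL = "Normal"
    LOW_RISK = "Low Risk"
    HIGH_RISK = "High Risk"
    OUT_OF_RANGE = "Out of Range"


@dataclass(frozen=True)
class AgeBand:
    """An age interval (lower, upper] with its CI cut-points.

    ``display`` holds the three reported CI ranges (safe, mild, unsafe)
    used for presentation and plausibility checks only; classification
    uses gamma and delta alone.
    """

    lower: float
    upper: float
    gamma: float
    delta: float
    display: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] = field(
        default=((0.0, 0.0), (0.0, 0.0), (0.0, 0.0))
    )

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"need lower < upper, got ({self.lower}, {self.upper})")
        if not self.gamma < self.delta:
            raise ValueError(f"need gamma < delta, got ({self.gamma}, {self.delta})")

    def contains(self, age: float) -> bool:
        return self.lower < age <= self.upper

    @property
    def label(self) -> str:
        return f"{self.lower:g}-{self.upper:g}"


@dataclass(frozen=True)
class ThresholdTable:
    """Per-age-group biomarker threshold template.

    ``rows`` maps biomarker name -> {"normal": (lo, hi), "low_risk": ...,
    "high_risk": ...}; ``direction`` maps biomarker name -> "higher-is-risk"
    or "lower-is-risk".  Threshold age groups are keyed by their own
    (lower, upper] interval, independent of the CI band registry (the two
    groupings genuinely differ).
    """

    age_group: str
    lower: float
    upper: float
    rows: Mapping[str, Mapping[str, tuple[float, float]]]
    direction: Mapping[str, str]

    def contains(self, age: float) -> bool:
        return self.lower < age <= self.upper


@dataclass(frozen=True)
class RiskAssessment:
    """One classified instance: its CI, zone, band and optional flags."""

    age: float
    ci: float
    zone: ZoneLabel
    band: AgeBand
    flags: Optional[Mapping[str, FlagLabel]] = None


@dataclass(frozen=True)
class ScreenResult:
    """Cohort screening output: per-zone counts plus every assessment."""

    counts: Mapping[str, int]
    assessments: tuple[RiskAssessment, ...]


@dataclass(frozen=True)
class InterventionWindow:
    """Crossing ages of a modeled CI trajectory.

    ``onset_age`` is the first age at which the trajectory leaves the Safe
    zone, ``unsafe_age`` the first age it enters the Unsafe zone; the
    intervention window is [onset_age, unsafe_age) (right end censored at
    the scanned range when the Unsafe zone is never reached).  ``window``
    is None when the trajectory never leaves Safe within the range, or
    when it is already Unsafe at the start (no window remains).
    """

    onset_age: Optional[float]
    unsafe_age: Optional[float]
    window: Optional[tuple[float, float]]


def _default_registry() -> tuple[AgeBand, ...]:
    from .defaults import DEFAULT_REGISTRY

    return DEFAULT_REGISTRY


def band_for_age(age: float, registry: Optional[Sequence[AgeBand]] = None) -> AgeBand:
    """Return the unique band with lower < age <= upper."""
    bands = _default_registry() if registry is None else registry
    for band in bands:
        if band.contains(age):
            return band
    raise ValueError(f"age {age!r} outside all registered bands")


def classify_ci(
    age: float, ci: float, registry: Optional[Sequence[AgeBand]] = None
) -> ZoneLabel:
    """Classify a CI score into Safe / Mild Risk / Unsafe for this age.

    Boundary convention follows the defining inequalities: a score exactly
    at gamma is Safe, exactly at delta is Mild Risk.  A score below the
    band's displayed Safe range still classifies Safe, with a logged
    plausibility warning.
    """
    band = band_for_age(age, registry)
    if ci <= band.gamma:
        safe_lo = band.display[0][0]
        if ci < safe_lo:
            logger.warning(
                "CI %.3g below the displayed Safe range %s for band %s",
                ci, band.display[0], band.label,
            )
        return ZoneLabel.SAFE
    if ci <= band.delta:
        return ZoneLabel.MILD_RISK
    return ZoneLabel.UNSAFE


def four_zone_label(
    age: float, ci: float, registry: Optional[Sequence[AgeBand]] = None
) -> str:
    """Optional four-zone relabeling: Normal / Mild Risk / High Risk / MCI.

    The Unsafe zone splits at the band's displayed unsafe upper edge into
    High Risk (below it) and MCI (above it); Safe maps to Normal.
    """
    band = band_for_age(age, registry)
    zone = classify_ci(age, ci, registry)
    if zone is ZoneLabel.SAFE:
        return "Normal"
    if zone is ZoneLabel.MILD_RISK:
        return "Mild Risk"
    return "High Risk" if ci <= band.display[2][1] else "MCI"


def _default_thresholds() -> tuple[ThresholdTable, ...]:
    from .defaults import DEFAULT_THRESHOLDS

    return DEFAULT_THRESHOLDS


_FLAG_ORDER = (
    ("normal", FlagLabel.NORMAL),
    ("low_risk", FlagLabel.LOW_RISK),
    ("high_risk", FlagLabel.HIGH_RISK),
)


def flag_biomarker(
    age_group: str,
    biomarker: str,
    value: float,
    tables: Optional[Sequence[ThresholdTable]] = None,
) -> FlagLabel:
    """Flag one biomarker value against an age group's threshold template.

    Ranges are half-open with the boundary falling into the next range
    along the risk direction: for higher-is-risk markers a range covers
    [lo, hi); for lower-is-risk markers (CSF A-beta-42) it covers (lo, hi].
    Values beyond the tabulated extremes flag High Risk on the risky side
    and Out of Range on the safe side.
    """
    tabs = _default_thresholds() if tables is None else tables
    table = next((t for t in tabs if t.age_group == age_group), None)
    if table is None:
        raise KeyError(f"unknown age group {age_group!r}")
    if biomarker not in table.rows:
        raise KeyError(f"unknown biomarker {biomarker!r} for group {age_group!r}")
    rows = table.rows[biomarker]
    higher_is_risk = table.direction.get(biomarker, "higher-is-risk") == "higher-is-risk"
    for key, label in _FLAG_ORDER:
        lo, hi = rows[key]
        inside = (lo <= value < hi) if higher_is_risk else (lo < value <= hi)
        if inside:
            return label
    hi_lo, hi_hi = rows["high_risk"]
    if higher_is_risk and value >= hi_hi:
        return FlagLabel.HIGH_RISK
    if not higher_is_risk and value <= hi_lo:
        return FlagLabel.HIGH_RISK
    return FlagLabel.OUT_OF_RANGE


def _flags_for_record(
    record: BiomarkerRecord, tables: Sequence[ThresholdTable]
) -> Optional[dict[str, FlagLabel]]:
    table = next((t for t in tables if t.contains(record.age)), None)
    if table is None:
        return None
    return {
        name: flag_biomarker(table.age_group, name, v, tables)
        for name, v in zip(BIOMARKERS, record.values)
        if name in table.rows
    }


def classify_instance(
    record: BiomarkerRecord,
    ci_params: CIParams,
    registry: Optional[Sequence[AgeBand]] = None,
    thresholds: Optional[Sequence[ThresholdTable]] = None,
) -> RiskAssessment:
    """Score one instance and classify it into its risk zone.

    Chains the observation-based CI score with the age-banded classifier;
    when threshold tables are supplied and one covers the instance's age,
    per-biomarker flags are attached.
    """
    ci = ci_from_observation(record, ci_params)
    band = band_for_age(record.age, registry)
    zone = classify_ci(record.age, ci, registry)
    flags = _flags_for_record(record, thresholds) if thresholds is not None else None
    return RiskAssessment(age=record.age, ci=ci, zone=zone, band=band, flags=flags)


def screen_cohort(
    cohort: CohortTable,
    ci_params: Optional[CIParams],
    registry: Optional[Sequence[AgeBand]] = None,
    thresholds: Optional[Sequence[ThresholdTable]] = None,
) -> ScreenResult:
    """Classify every cohort instance and tally the zones.

    With ``ci_params=None`` the cohort frame must carry a precomputed
    ``CI`` column, which is used verbatim (supporting tables that already
    report scores); otherwise CI is computed from the observations.
    Counts always sum to the cohort size and are order-invariant.
    """
    df = cohort.df
    if ci_params is None:
        if CI_COLUMN not in df.columns:
            raise ValueError("ci_params is None and cohort has no CI column")
        ci_values = df[CI_COLUMN].to_numpy(dtype=float)
    else:
        ci_values = score_cohort(cohort, ci_params)
    assessments = []
    counts = {z.value: 0 for z in ZoneLabel}
    records = cohort.records
    ages = df[AGE_COLUMN].to_numpy(dtype=float)
    for i, (age, ci) in enumerate(zip(ages, ci_values)):
        band = band_for_age(age, registry)
        zone = classify_ci(age, ci, registry)
        flags = None
        if thresholds is not None and i < len(records):
            flags = _flags_for_record(records[i], thresholds)
        assessments.append(
            RiskAssessment(age=float(age), ci=float(ci), zone=zone, band=band, flags=flags)
        )
        counts[zone.value] += 1
    return ScreenResult(counts=counts, assessments=tuple(assessments))


def safe_biomarker_bounds(
    age: float,
    ci_params: CIParams,
    registry: Optional[Sequence[AgeBand]] = None,
    vary: str = "CSF_Ab42",
    fixed: Optional[Mapping[str, float]] = None,
) -> Optional[tuple[float, float]]:
    """Range of one biomarker keeping an instance Safe, others held fixed.

    Solves alpha*exp(beta*A) + sum_i w_i * B_i <= gamma for the varied
    biomarker.  A positive weight yields an upper limit [0, b]; a negative
    (protective) weight yields a lower limit [b, inf).  Returns None when
    no non-negative value can keep the instance Safe.
    """
    if vary not in BIOMARKERS:
        raise KeyError(f"unknown biomarker {vary!r}")
    fixed = dict(fixed or {})
    others = [b for b in BIOMARKERS if b != vary]
    missing = [b for b in others if b not in fixed]
    if missing:
        raise KeyError(f"missing fixed value(s) for {missing}")
    band = band_for_age(age, registry)
    w = dict(zip(BIOMARKERS, ci_params.weights))
    if w[vary] == 0:
        raise ValueError(f"weight for {vary!r} is zero; bound undefined")
    budget = band.gamma - ci_params.alpha * math.exp(ci_params.beta * age)
    budget -= sum(w[b] * fixed[b] for b in others)
    bound = float(budget / w[vary])
    if w[vary] > 0:
        if bound < 0:
            return None
        return (0.0, bound)
    return (max(bound, 0.0), math.inf)


def _bisect_crossing(lo, hi, predicate, tol=1e-6):
    """First age in (lo, hi] where predicate flips True, to tolerance tol."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return hi


def intervention_window(
    ci_params: CIParams,
    registry: Optional[Sequence[AgeBand]] = None,
    age_range: tuple[float, float] = (31.0, 70.0),
    step: float = 0.1,
) -> InterventionWindow:
    """Locate Safe-exit and Unsafe-entry ages of the modeled CI trajectory.

    The model-based CI is scanned over ``age_range`` at resolution
    ``step``; each detected crossing is refined by bisection to 1e-6
    years.  Useful retrospectively: for an individual presenting late, the
    window estimates when intervention would have been most valuable.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    lo, hi = float(age_range[0]), float(age_range[1])
    grid = np.arange(lo, hi + step / 2, step)
    grid = grid[grid <= hi]
    if grid.size == 0 or grid[-1] < hi:
        grid = np.append(grid, hi)

    def rank(age: float) -> int:
        return classify_ci(age, float(ci_from_age(age, ci_params)), registry).rank

    ranks = np.array([rank(a) for a in grid])

    def first_crossing(threshold: int) -> Optional[float]:
        idx = np.nonzero(ranks >= threshold)[0]
        if idx.size == 0:
            return None
        i = int(idx[0])
        if i == 0:
            return float(grid[0])
        return float(
            _bisect_crossing(grid[i - 1], grid[i], lambda a: rank(a) >= threshold)
        )

    onset = first_crossing(1)
    unsafe = first_crossing(2)
    if onset is None:
        return InterventionWindow(onset_age=None, unsafe_age=None, window=None)
    if unsafe is not None and unsafe <= onset:
        # already Unsafe at (or before) Safe exit: no window remains
        return InterventionWindow(onset_age=onset, unsafe_age=unsafe, window=None)
    window_hi = unsafe if unsafe is not None else hi
    return InterventionWindow(onset_age=onset, unsafe_age=unsafe, window=(onset, window_hi))
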