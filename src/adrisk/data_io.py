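"""Cohort CSV input/output, validation, aggregation and imputation.

The on-disk format is a plain comma-separated table with header
``Age,CSF_Ab42,Amyloid_PET,CSF_Tau,MRI_FDG_PET`` (optionally ``CI`` and
``Risk_Level``).  Header matching is case-insensitive and tolerant of the
spelling variants found in practice (``CSF_Aβ42``, ``CSF Ab42``,
``MRI FDG PET``, ...); the canonical names are always emitted on write.

Stage-1 cleaning follows two rules: instances are identified by age, so
rows sharing an age (after rounding to the nearest year) are collapsed to
their arithmetic mean; and gaps in the age grid — whole missing ages or
individual missing cells — are filled from the sigmoid trajectory model,
with filled rows flagged as synthetic.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .cohort import (
    AGE_COLUMN,
    AGE_MAX,
    AGE_MIN,
    BIOMARKERS,
    CI_COLUMN,
    COLUMNS,
    RISK_COLUMN,
    SYNTHETIC_COLUMN,
    BiomarkerRecord,
    CohortTable,
)
from .sigmoid import NoiseSpec, SigmoidParams, sigmoid, simulate_trajectory

__all__ = [
    "read_cohort",
    "write_cohort",
    "aggregate_duplicates",
    "impute_missing_ages",
    "BiomarkerRecord",
    "CohortTable",
]

logger = logging.getLogger(__name__)

_ALIASES = {
    "age": AGE_COLUMN,
    "csfab42": "CSF_Ab42",
    "csfabeta42": "CSF_Ab42",
    "csfamyloidbeta42": "CSF_Ab42",
    "amyloidpet": "Amyloid_PET",
    "csftau": "CSF_Tau",
    "mrifdgpet": "MRI_FDG_PET",
    "mrifogpet": "MRI_FDG_PET",  # typo seen in source tables
    "ci": CI_COLUMN,
    "cognitiveimpairment": CI_COLUMN,
    "ciscore": CI_COLUMN,
    "risklevel": RISK_COLUMN,
    "riskzone": RISK_COLUMN,
    "synthetic": SYNTHETIC_COLUMN,
}


def _normalize_header(name: str) -> str:
    key = name.strip().lower().replace("β", "b")  # β -> b
    key = re.sub(r"[^0-9a-z]", "", key)
    return _ALIASES.get(key, name.strip())


def read_cohort(path: Union[str, Path], strict: bool = False) -> CohortTable:
    """Read a cohort CSV, validating ages and biomarker values.

    In strict mode any missing or invalid cell raises.  Otherwise rows with
    an out-of-range age or a negative/non-finite biomarker are dropped with
    a logged warning, while empty cells are retained as NaN for later
    sigmoid-based filling by :func:`impute_missing_ages`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    raw = pd.read_csv(path)
    raw = raw.rename(columns=_normalize_header)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")

    keep = [c for c in list(COLUMNS) + [CI_COLUMN, RISK_COLUMN, SYNTHETIC_COLUMN] if c in raw.columns]
    df = raw[keep].copy()
    numeric = [c for c in keep if c not in (RISK_COLUMN, SYNTHETIC_COLUMN)]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            if strict:
                raise ValueError(
                    f"{path.name}: non-numeric value(s) in {col!r} at rows "
                    f"{list(df.index[bad])}"
                )
            for i in df.index[bad]:
                logger.warning("%s: non-numeric %s=%r at row %d treated as missing",
                               path.name, col, df.at[i, col], i)
        df[col] = coerced

    age = df[AGE_COLUMN]
    bad_age = age.isna() | (age < AGE_MIN) | (age > AGE_MAX)
    bad_marker = pd.Series(False, index=df.index)
    for col in BIOMARKERS:
        v = df[col]
        bad_marker |= (v < 0) | np.isinf(v)
    if strict:
        if bad_age.any():
            raise ValueError(
                f"{path.name}: age(s) outside [{AGE_MIN:g}, {AGE_MAX:g}] at rows "
                f"{list(df.index[bad_age])}"
            )
        if bad_marker.any():
            raise ValueError(
                f"{path.name}: negative or non-finite biomarker value(s) at rows "
                f"{list(df.index[bad_marker])}"
            )
        if df[list(BIOMARKERS)].isna().any().any():
            na_rows = list(df.index[df[list(BIOMARKERS)].isna().any(axis=1)])
            raise ValueError(f"{path.name}: missing biomarker cell(s) at rows {na_rows}")
    else:
        drop = bad_age | bad_marker
        for i in df.index[drop]:
            logger.warning("%s: dropped invalid row %d (Age=%r)", path.name, i, age.get(i))
        df = df.loc[~drop]
        for col in BIOMARKERS:
            for i in df.index[df[col].isna()]:
                logger.warning("%s: missing cell %s at row %d (kept for imputation)",
                               path.name, col, i)
    df = df.reset_index(drop=True)
    return CohortTable(df=df, provenance=str(path))


def write_cohort(
    cohort: CohortTable,
    path: Union[str, Path],
    float_format: str = "%.9g",
    include_flags: bool = False,
) -> None:
    """Write a cohort CSV with canonical headers.

    Floats are printed with 9 significant digits so read/write round-trips
    preserve source precision.  The internal ``synthetic`` flag column is
    only emitted when ``include_flags`` is set.
    """
    df = cohort.df
    cols = [c for c in list(COLUMNS) + [CI_COLUMN, RISK_COLUMN] if c in df.columns]
    if include_flags and SYNTHETIC_COLUMN in df.columns:
        cols.append(SYNTHETIC_COLUMN)
    df[cols].to_csv(path, index=False, float_format=float_format)


def aggregate_duplicates(cohort: CohortTable) -> CohortTable:
    """Collapse rows sharing an age into one averaged record.

    Age is the instance identifier; ages are rounded to the nearest year
    for duplicate detection and the group key becomes the output age.
    Biomarker (and CI) columns take the arithmetic mean, ignoring missing
    cells; the synthetic flag propagates by any().  Output is sorted by
    age with unique ages — the operation is idempotent.
    """
    df = cohort.df
    if not len(df):
        return cohort.copy()
    key = np.rint(df[AGE_COLUMN].to_numpy(dtype=float))
    value_cols = [c for c in list(BIOMARKERS) + [CI_COLUMN] if c in df.columns]
    agg: dict[str, str] = {c: "mean" for c in value_cols}
    if SYNTHETIC_COLUMN in df.columns:
        agg[SYNTHETIC_COLUMN] = "any"
    out = df.groupby(key).agg(agg)
    out.insert(0, AGE_COLUMN, out.index.to_numpy(dtype=float))
    out = out.sort_index().reset_index(drop=True)
    n_merged = len(df) - len(out)
    if n_merged:
        logger.info("aggregated %d duplicate row(s) by age", n_merged)
    return CohortTable(df=out, provenance=cohort.provenance)


def impute_missing_ages(
    cohort: CohortTable,
    params: Mapping[str, SigmoidParams],
    age_range: tuple[int, int],
    noise: Optional[NoiseSpec] = None,
) -> CohortTable:
    """Fill age gaps (and missing cells) from the sigmoid trajectory model.

    Every integer age in the closed ``age_range`` absent from the cohort
    gains a synthetic record drawn from :func:`simulate_trajectory`; with
    ``noise=None`` the filled values equal S(age) exactly.  Missing single
    cells in existing rows are filled from the same model (deterministic
    S(age)) so one mechanism covers both kinds of gap.  Synthetic rows are
    flagged in the ``synthetic`` column and in provenance.
    """
    missing_params = [b for b in BIOMARKERS if b not in params]
    if missing_params:
        raise KeyError(f"missing sigmoid params for {missing_params}")
    lo, hi = int(age_range[0]), int(age_range[1])
    df = cohort.df.copy()
    if SYNTHETIC_COLUMN not in df.columns:
        df[SYNTHETIC_COLUMN] = False

    # fill individual missing cells deterministically from the model
    for col in BIOMARKERS:
        mask = df[col].isna()
        if mask.any():
            fill = np.maximum(
                np.asarray(sigmoid(df.loc[mask, AGE_COLUMN].to_numpy(dtype=float), params[col])),
                0.0,
            )
            df.loc[mask, col] = fill
            for i, v in zip(df.index[mask], np.atleast_1d(fill)):
                logger.info("filled missing %s at age %g with model value %.6g",
                            col, df.at[i, AGE_COLUMN], v)

    present = set(int(a) for a in np.rint(df[AGE_COLUMN].dropna().to_numpy(dtype=float)))
    gaps = [a for a in range(lo, hi + 1) if a not in present]
    if gaps:
        ages = np.asarray(gaps, dtype=float)
        children = np.random.SeedSequence(noise.seed if noise else 0).spawn(len(BIOMARKERS))
        new_cols: dict[str, np.ndarray] = {AGE_COLUMN: ages}
        for child, name in zip(children, BIOMARKERS):
            new_cols[name] = simulate_trajectory(
                ages, params[name], noise, rng=np.random.default_rng(child)
            )
        new = pd.DataFrame(new_cols)
        new[SYNTHETIC_COLUMN] = True
        df = pd.concat([df, new], ignore_index=True)
        logger.info("imputed %d missing age(s) in [%d, %d]", len(gaps), lo, hi)
    df = df.sort_values(AGE_COLUMN, kind="mergesort").reset_index(drop=True)
    prov = cohort.provenance
    if gaps:
        prov = f"{prov}+imputed({len(gaps)} ages)" if prov else f"imputed({len(gaps)} ages)"
    return CohortTable(df=df, provenance=prov)
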