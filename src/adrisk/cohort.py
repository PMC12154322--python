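"""In-memory cohort containers.

A cohort is a cross-sectional table of individuals, one row per instance,
with an age and four numeric biomarker measurements: CSF amyloid-beta 42
(protective; low values mark amyloid deposition), amyloid PET burden,
CSF Tau (neurodegeneration), and a combined MRI/FDG-PET structural-metabolic
composite.  Ages from 10 to 110 years are accepted so that preclinical
trajectories in young adults can be represented alongside elderly cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List

import pandas as pd

AGE_COLUMN = "Age"
BIOMARKERS = ("CSF_Ab42", "Amyloid_PET", "CSF_Tau", "MRI_FDG_PET")
COLUMNS = (AGE_COLUMN,) + BIOMARKERS
CI_COLUMN = "CI"
RISK_COLUMN = "Risk_Level"
SYNTHETIC_COLUMN = "synthetic"

AGE_MIN = 10.0
AGE_MAX = 110.0


@dataclass(frozen=True)
class BiomarkerRecord:
    """One individual's age and biomarker panel.

    Values are stored verbatim in whatever unit system the source table
    uses; no unit conversion is attempted (see the threshold configuration
    for the two reference scales shipped with the package).
    """

    age: float
    csf_ab42: float
    amyloid_pet: float
    csf_tau: float
    mri_fdg_pet: float
    synthetic: bool = False

    def __post_init__(self) -> None:
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise ValueError(
                f"age {self.age!r} outside supported range "
                f"[{AGE_MIN:g}, {AGE_MAX:g}]"
            )
        for name in ("csf_ab42", "amyloid_pet", "csf_tau", "mri_fdg_pet"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name}={v!r} must be finite and >= 0")

    @property
    def values(self) -> tuple[float, float, float, float]:
        """Biomarker values in canonical column order."""
        return (self.csf_ab42, self.amyloid_pet, self.csf_tau, self.mri_fdg_pet)


_FIELD_FOR_COLUMN = {
    "CSF_Ab42": "csf_ab42",
    "Amyloid_PET": "amyloid_pet",
    "CSF_Tau": "csf_tau",
    "MRI_FDG_PET": "mri_fdg_pet",
}


@dataclass
class CohortTable:
    """A cohort as a pandas DataFrame with canonical columns.

    The frame always carries ``Age`` and the four biomarker columns; it may
    additionally carry ``CI``, ``Risk_Level`` and a boolean ``synthetic``
    flag marking imputed/simulated rows.  ``provenance`` is a free-text tag
    describing where the rows came from.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(COLUMNS)))
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ages(self) -> pd.Series:
        return self.df[AGE_COLUMN]

    @property
    def records(self) -> List[BiomarkerRecord]:
        """Rows as validated records; rows with missing cells are skipped."""
        out: List[BiomarkerRecord] = []
        syn = (
            self.df[SYNTHETIC_COLUMN]
            if SYNTHETIC_COLUMN in self.df.columns
            else pd.Series(False, index=self.df.index)
        )
        for idx, row in self.df.iterrows():
            vals = [row[c] for c in COLUMNS]
            if any(pd.isna(v) for v in vals):
                continue
            out.append(
                BiomarkerRecord(
                    age=float(row[AGE_COLUMN]),
                    csf_ab42=float(row["CSF_Ab42"]),
                    amyloid_pet=float(row["Amyloid_PET"]),
                    csf_tau=float(row["CSF_Tau"]),
                    mri_fdg_pet=float(row["MRI_FDG_PET"]),
                    synthetic=bool(syn.loc[idx]),
                )
            )
        return out

    @classmethod
    def from_records(
        cls, records: Iterable[BiomarkerRecord], provenance: str = ""
    ) -> "CohortTable":
        rows = [
            {
                AGE_COLUMN: r.age,
                "CSF_Ab42": r.csf_ab42,
                "Amyloid_PET": r.amyloid_pet,
                "CSF_Tau": r.csf_tau,
                "MRI_FDG_PET": r.mri_fdg_pet,
                SYNTHETIC_COLUMN: r.synthetic,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(COLUMNS) + [SYNTHETIC_COLUMN])
        return cls(df=df, provenance=provenance)

    def copy(self) -> "CohortTable":
        return CohortTable(df=self.df.copy(), provenance=self.provenance)
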