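"""Default (illustrative) parameter sets, band registry and thresholds.

The band registry and threshold templates are the package's canonical
reference configuration.  The sigmoid trajectory parameters and CI model
parameters are *illustrative*: they are chosen so the four curves show the
qualitative shapes expected in ageing cohorts on the template threshold
scale (CSF A-beta-42 falling with age; amyloid PET, CSF Tau and the
MRI/FDG-PET composite rising) and so the modeled CI stays within the
displayed band ranges over midlife — they are configuration, not clinical
constants, and any scientific use requires an explicit calibrated set.

A second, clearly separated reference block carries published clinical
cut-offs on the pg/mL scale (CSF A-beta-42 480/800 pg/mL, age-dependent
CSF Tau limits, the Centiloid scale); it is never mixed with the template
scale above, as no conversion between the two is defined.
"""

from __future__ import annotations

from .ci import CIParams, TermParams
from .sigmoid import NoiseSpec, SigmoidParams
from .zones import AgeBand, ThresholdTable

__all__ = [
    "DEFAULT_SIGMOID_PARAMS",
    "DEFAULT_NOISE",
    "DEFAULT_NOISE_SCALES",
    "DEFAULT_TAU_COUPLING",
    "DEFAULT_CI_PARAMS",
    "DEFAULT_REGISTRY",
    "DEFAULT_THRESHOLDS",
    "CLINICAL_REFERENCE_PGML",
]

# Illustrative age trajectories on the template threshold scale.
# Decreasing curves use k > 0, increasing curves k < 0.
DEFAULT_SIGMOID_PARAMS: dict[str, SigmoidParams] = {
    "CSF_Ab42": SigmoidParams(L=22.0, k=0.08, x0=60.0),
    "Amyloid_PET": SigmoidParams(L=20.0, k=-0.08, x0=50.0),
    "CSF_Tau": SigmoidParams(L=16.0, k=-0.08, x0=50.0),
    "MRI_FDG_PET": SigmoidParams(L=14.0, k=-0.08, x0=55.0),
}

# Additive measurement noise, sd = 5% of each curve's plateau.
DEFAULT_NOISE_SCALES: dict[str, float] = {
    "CSF_Ab42": 1.1,
    "Amyloid_PET": 1.0,
    "CSF_Tau": 0.8,
    "MRI_FDG_PET": 0.7,
}
DEFAULT_NOISE = NoiseSpec(kind="additive-gaussian", scale=1.0, seed=0)

# Negative coupling reproducing the inverse A-beta-42 / Tau relationship.
DEFAULT_TAU_COUPLING = -0.5

# Illustrative CI parameters (term order: Ab42, PET, Tau, FDG-PET).
# The protective direction of A-beta-42 is carried by w < 0 with m > 0;
# rising markers take m < 0.
DEFAULT_CI_PARAMS = CIParams(
    alpha=0.5,
    beta=0.04,
    terms=(
        TermParams(w=-0.05, k=30.0, m=0.02),
        TermParams(w=0.10, k=1.5, m=-0.03),
        TermParams(w=0.10, k=1.2, m=-0.03),
        TermParams(w=0.10, k=1.0, m=-0.03),
    ),
)

# Age-banded CI cut-points: (gamma, delta) per (lower, upper] band, with
# the displayed Safe / Mild / Unsafe ranges used for reporting.
DEFAULT_REGISTRY: tuple[AgeBand, ...] = (
    AgeBand(30, 40, gamma=3, delta=6, display=((0, 3), (3, 6), (6, 10))),
    AgeBand(40, 50, gamma=4, delta=7, display=((1, 4), (4, 7), (7, 12))),
    AgeBand(50, 60, gamma=5, delta=8, display=((1.5, 5), (5, 8), (8, 13))),
    AgeBand(60, 70, gamma=6, delta=9, display=((2, 6), (6, 9), (9, 14))),
)

_DIRECTION = {
    "CSF_Ab42": "lower-is-risk",
    "Amyloid_PET": "higher-is-risk",
    "CSF_Tau": "higher-is-risk",
    "MRI_FDG_PET": "higher-is-risk",
}

DEFAULT_THRESHOLDS: tuple[ThresholdTable, ...] = (
    ThresholdTable(
        age_group="30-40",
        lower=30,
        upper=40,
        rows={
            "CSF_Ab42": {"normal": (15, 22), "low_risk": (10, 15), "high_risk": (5, 10)},
            "Amyloid_PET": {"normal": (4, 7), "low_risk": (7, 10), "high_risk": (10, 15)},
            "CSF_Tau": {"normal": (3, 6), "low_risk": (6, 9), "high_risk": (9, 12)},
            "MRI_FDG_PET": {"normal": (2, 5), "low_risk": (5, 8), "high_risk": (8, 12)},
        },
        direction=_DIRECTION,
    ),
    ThresholdTable(
        age_group="40-50",
        lower=40,
        upper=50,
        rows={
            "CSF_Ab42": {"normal": (12, 18), "low_risk": (8, 12), "high_risk": (5, 8)},
            "Amyloid_PET": {"normal": (5, 9), "low_risk": (9, 12), "high_risk": (12, 18)},
            "CSF_Tau": {"normal": (4, 7), "low_risk": (7, 10), "high_risk": (10, 14)},
            "MRI_FDG_PET": {"normal": (3, 6), "low_risk": (6, 9), "high_risk": (9, 13)},
        },
        direction=_DIRECTION,
    ),
    ThresholdTable(
        age_group="55-65",
        lower=55,
        upper=65,
        rows={
            "CSF_Ab42": {"normal": (10, 15), "low_risk": (6, 10), "high_risk": (3, 6)},
            "Amyloid_PET": {"normal": (7, 12), "low_risk": (12, 16), "high_risk": (16, 22)},
            "CSF_Tau": {"normal": (5, 8), "low_risk": (8, 12), "high_risk": (12, 16)},
            "MRI_FDG_PET": {"normal": (4, 7), "low_risk": (7, 10), "high_risk": (10, 15)},
        },
        direction=_DIRECTION,
    ),
)

# Published clinical reference cut-offs on the pg/mL / Centiloid scale.
# Kept strictly separate from the template-scale thresholds above.
CLINICAL_REFERENCE_PGML: dict = {
    "CSF_Ab42": {
        "units": "pg/mL",
        "low_cutoff": 480.0,       # below: amyloid-plaque accumulation
        "normal_range": (600.0, 800.0),
        "high_normal": 800.0,      # above: typical of normal cognition
        "direction": "lower-is-risk",
    },
    "CSF_Tau": {
        "units": "pg/mL",
        "age_limits": {"21-50": 300.0, "51-70": 450.0},
        "direction": "higher-is-risk",
    },
    "Amyloid_PET": {
        "units": "Centiloid",
        "young_normal": 0.0,
        "mild_neurodegeneration": 100.0,
        "direction": "higher-is-risk",
    },
}
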