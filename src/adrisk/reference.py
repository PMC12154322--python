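"""Bundled worked example: eight classified instances.

A small reference panel of eight individuals (ages 34-58) with measured
biomarker values on the pg/mL-like source scale, their composite CI scores
and the risk zones assigned by the age-banded classifier.  It is used in
the documentation, the test suite and the reproduction script: re-feeding
the (Age, CI) pairs through :func:`adrisk.zones.classify_ci` with the
default registry must reproduce every label (2 Safe, 6 Mild Risk).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["worked_example"]

_ROWS = [
    # Age, CSF_Ab42, Amyloid_PET, CSF_Tau, MRI_FDG_PET, CI, Risk_Level
    (58, 428.21, 14.28, 382.99, 6.92, 3.18, "Safe"),
    (40, 411.53, 19.13, 370.31, 14.58, 3.37, "Mild Risk"),
    (53, 516.39, 8.62, 478.00, 3.19, 3.21, "Safe"),
    (39, 413.08, 14.25, 403.98, 6.57, 4.41, "Mild Risk"),
    (34, 422.18, 15.37, 393.98, 6.55, 3.62, "Mild Risk"),
    (47, 427.23, 14.69, 411.34, 6.29, 5.30, "Mild Risk"),
    (48, 419.70, 14.01, 414.07, 6.95, 4.21, "Mild Risk"),
    (50, 418.06, 15.26, 399.28, 7.18, 5.35, "Mild Risk"),
]


def worked_example() -> pd.DataFrame:
    """Return the eight-instance worked example as a fresh DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["Age", "CSF_Ab42", "Amyloid_PET", "CSF_Tau", "MRI_FDG_PET", "CI", "Risk_Level"],
    ).astype({"Age": float})
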