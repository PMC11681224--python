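"""Small bundled datasets.

Currently the demographic and trial-time table of the five-sprinter cohort
(3 male, 2 female collegiate athletes) on which the tracking system's
concurrent validity was assessed: two maximal 100-m trials per athlete,
timed to the millisecond.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["validation_cohort"]

_COHORT_ROWS = [
    # participant, gender, age (y), height (cm), weight (kg), BMI, t1 (s), t2 (s)
    ("S1", "M", 20, 168, 68, 24.1, 14.211, 13.955),
    ("S2", "M", 20, 171, 72, 24.6, 14.317, 17.680),
    ("S3", "M", 22, 180, 73, 22.5, 16.724, 16.876),
    ("S4", "F", 22, 151, 43, 18.9, 21.219, 20.143),
    ("S5", "F", 22, 160, 48, 18.8, 16.937, 17.470),
]


def validation_cohort() -> pd.DataFrame:
    """The five-athlete validation cohort: demographics and 100-m trial times."""
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "participant",
            "gender",
            "age_years",
            "height_cm",
            "weight_kg",
            "bmi_kg_m2",
            "time_trial1_s",
            "time_trial2_s",
        ],
    )
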