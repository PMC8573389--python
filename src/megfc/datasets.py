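"""Reference tables bundled with the package.

``cae_clinical_table`` is the clinical characteristics table of the
22-patient childhood absence epilepsy cohort whose study design the synthetic
generator emulates (sex, age in years, disease duration in months, seizure
frequency in times/day).  It is the default clinical table for the bundled
study designs and the input to the clinical-summary computations.
"""

from __future__ import annotations

import pandas as pd

# patient, sex, age (years), duration of disease (months), seizure frequency (times/day)
_CAE_CLINICAL = [
    (1, "M", 10, 5, 6),
    (2, "F", 6, 5, 2),
    (3, "F", 6, 5, 2),
    (4, "F", 7, 5, 10),
    (5, "M", 8, 6, 10),
    (6, "F", 9, 5, 10),
    (7, "M", 8, 6, 7),
    (8, "F", 5, 6, 2),
    (9, "F", 10, 12, 5),
    (10, "F", 8, 16, 5),
    (11, "F", 9, 14, 5),
    (12, "F", 10, 11, 6),
    (13, "F", 10, 12, 8),
    (14, "F", 11, 23, 8),
    (15, "F", 10, 32, 8),
    (16, "F", 5, 3, 8),
    (17, "F", 8, 8, 8),
    (18, "M", 8, 5, 20),
    (19, "F", 7, 4, 20),
    (20, "F", 9, 12, 4),
    (21, "M", 8, 4, 15),
    (22, "M", 9, 15, 18),
]


def cae_clinical_table() -> pd.DataFrame:
    """Clinical table of the reference 22-patient CAE cohort."""
    return pd.DataFrame(
        _CAE_CLINICAL,
        columns=["patient", "sex", "age_years", "duration_months", "seizure_freq_per_day"],
    )
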