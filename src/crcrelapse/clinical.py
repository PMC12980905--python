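"""Cohort-level clinical descriptors.

The nine-patient CRLM cohort (eight MSS, one MSI) with the interval, in
months, between resection of the first liver metastasis and detection of the
relapse. These published per-patient values are inputs to the descriptive
cohort statistics; no sequencing data is needed to compute them.
"""

import pandas as pd

TIME_TO_RELAPSE_MONTHS = {
    "Patient 1": 32,
    "Patient 2": 13,
    "Patient 3": 11,
    "Patient 4": 14,
    "Patient 5": 7,
    "Patient 6": 13,
    "Patient 7": 14,
    "Patient 8": 1,
    "Patient MSI": 16,
}


def cohort_table() -> pd.DataFrame:
    """Return the cohort overview as a patient-indexed DataFrame."""
    return pd.DataFrame(
        {"time_to_relapse_months": pd.Series(TIME_TO_RELAPSE_MONTHS)}
    )


def mean_time_to_relapse(rounded: bool = True) -> float:
    """Mean time to relapse across the cohort, in months.

    With ``rounded=True`` (default) the value is rounded to the nearest
    whole month, the resolution at which the clinical course is recorded.
    """
    mean = cohort_table()["time_to_relapse_months"].mean()
    return float(round(mean)) if rounded else float(mean)
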