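"""Published cohort summaries used as worked inputs.

``REFERENCE_COHORT`` holds the demographics table of the 172-participant
three-group epilepsy cohort (52 healthy controls, 56 frontal-lobe and 64
temporal-lobe epilepsy patients) whose design the synthetic generator
emulates: printed contingency tables for the categorical variables and
per-group (n, mean, SD) summaries for the normally distributed continuous
variables.  These printed values are inputs to the cohort-statistics
routines; recomputing the reported test statistics from them exercises
:mod:`taskgrad.clinstats` against independently published numbers.
"""

from __future__ import annotations

#: Rows: CTR, FLE, TLE (or FLE, TLE for patient-only variables).
REFERENCE_COHORT = {
    "groups": ("CTR", "FLE", "TLE"),
    "n": (52, 56, 64),
    # continuous, mean (SD) per group
    "age_years": [(52, 34.1, 10.4), (56, 33.4, 10.2), (64, 39.2, 10.7)],
    # categorical contingency tables, rows = groups in listed order
    "sex_female_male": {
        "groups": ("CTR", "FLE", "TLE"),
        "counts": [[30, 22], [29, 27], [44, 20]],
    },
    "side_left_right": {
        "groups": ("FLE", "TLE"),
        "counts": [[30, 26], [34, 30]],
    },
    "fbtcs_yes_no": {
        "groups": ("FLE", "TLE"),
        "counts": [[31, 23], [20, 44]],
    },
    "topiramate_zonisamide_yes_no": {
        "groups": ("FLE", "TLE"),
        "counts": [[15, 41], [12, 52]],
    },
    "levetiracetam_yes_no": {
        "groups": ("FLE", "TLE"),
        "counts": [[29, 27], [41, 23]],
    },
}

#: Reported statistics for the same rows, at the precision they were
#: published (chi-square for categorical, one-way ANOVA F for age).
REFERENCE_STATISTICS = {
    "age_anova_f": 5.6,
    "sex_chi2": 3.7,
    "side_chi2": 0.0,
    "fbtcs_chi2": 8.2,
    "topiramate_zonisamide_chi2": 1.1,
    "levetiracetam_chi2": 1.9,
}
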