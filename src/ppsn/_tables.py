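"""Published summary values used as worked-example inputs.

These are the printed per-marker ROC rows, univariate odds-ratio rows, and
the FIGO-stage cross-tabulation from the source study's summary tables.
Patient-level data were never deposited, so the reproduction harness works
backwards from these: the 2x2 counts behind each row are reconstructed
from the printed sensitivity/specificity and the complete-case group sizes
(pre-treatment: 43 dead / 24 alive; post-NACT: 44 dead / 28 alive), then
every derived quantity is recomputed and compared to the printed one under
the two-decimal truncation display rule.
"""

from __future__ import annotations

# complete-case group sizes (events = dead, non-events = alive)
PRE_N_DEAD, PRE_N_ALIVE = 43, 24
POST_N_DEAD, POST_N_ALIVE = 44, 28

#: Per-marker ROC rows: printed AUC, p, cutoff, Se, Sp, PPV, NPV.
ROC_ROWS = [
    {
        "timepoint": "pre", "marker": "neutrophil_pct", "direction": "high_abnormal",
        "auc": 0.655, "p": 0.036, "cutoff": 73.40,
        "sensitivity": 0.628, "specificity": 0.750, "ppv": 81.81, "npv": 52.94,
    },
    {
        "timepoint": "pre", "marker": "lymphocyte_pct", "direction": "low_abnormal",
        "auc": 0.657, "p": 0.034, "cutoff": 14.15,
        "sensitivity": 0.442, "specificity": 0.917, "ppv": 90.47, "npv": 47.82,
    },
    {
        "timepoint": "pre", "marker": "lymphocyte_count", "direction": "low_abnormal",
        "auc": 0.677, "p": 0.017, "cutoff": 10.67,
        "sensitivity": 0.535, "specificity": 0.875, "ppv": 88.46, "npv": 51.21,
    },
    {
        "timepoint": "post", "marker": "neutrophil_pct", "direction": "high_abnormal",
        "auc": 0.669, "p": 0.016, "cutoff": 47.65,
        "sensitivity": 0.614, "specificity": 0.679, "ppv": 75.00, "npv": 52.77,
    },
    {
        "timepoint": "post", "marker": "lymphocyte_pct", "direction": "low_abnormal",
        "auc": 0.672, "p": 0.015, "cutoff": 41.35,
        "sensitivity": 0.727, "specificity": 0.571, "ppv": 72.72, "npv": 57.14,
    },
    {
        "timepoint": "post", "marker": "lymphocyte_count", "direction": "low_abnormal",
        "auc": 0.688, "p": 0.007, "cutoff": 16.84,
        "sensitivity": 0.909, "specificity": 0.500, "ppv": 74.07, "npv": 77.77,
    },
    {
        "timepoint": "post", "marker": "platelet_count", "direction": "low_abnormal",
        "auc": 0.657, "p": 0.026, "cutoff": 17.35,
        "sensitivity": 0.545, "specificity": 0.750, "ppv": 77.41, "npv": 51.21,
    },
]

#: Printed univariate odds ratios (point, 95% Wald bounds) per marker row.
UNIVARIATE_OR_ROWS = {
    ("pre", "neutrophil_pct"): {"or": 5.06, "ci_low": 1.66, "ci_high": 15.38},
    ("pre", "lymphocyte_pct"): {"or": 8.70, "ci_low": 1.81, "ci_high": 41.76},
    ("pre", "lymphocyte_count"): {"or": 8.05, "ci_low": 2.08, "ci_high": 31.05},
    ("post", "neutrophil_pct"): {"or": 3.35, "ci_low": 1.23, "ci_high": 9.10},
    ("post", "lymphocyte_pct"): {"or": 3.55, "ci_low": 1.30, "ci_high": 9.66},
    ("post", "lymphocyte_count"): {"or": 10.00, "ci_low": 2.81, "ci_high": 35.50},
    ("post", "platelet_count"): {"or": 3.60, "ci_low": 1.27, "ci_high": 10.19},
}

#: FIGO stage by vital status (live, dead) counts from the cohort table.
FIGO_COUNTS = {2: (1, 0), 3: (21, 28), 4: (6, 16)}

#: Printed FIGO stage-IV univariate odds ratio.
FIGO_OR = {"or": 2.09, "ci_low": 0.70, "ci_high": 6.24}


def reconstruct_counts(row: dict) -> tuple[int, int, int, int]:
    """2x2 counts (tp, fp, fn, tn) behind one printed ROC row.

    tp = round(Se * n_dead) and tn = round(Sp * n_alive) on that row's
    complete-case denominators; the reconstruction is validated by
    recomputing Se/Sp and matching the printed three decimals.
    """
    n_dead, n_alive = (
        (PRE_N_DEAD, PRE_N_ALIVE) if row["timepoint"] == "pre" else (POST_N_DEAD, POST_N_ALIVE)
    )
    tp = round(row["sensitivity"] * n_dead)
    tn = round(row["specificity"] * n_alive)
    return tp, n_alive - tn, n_dead - tp, tn
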