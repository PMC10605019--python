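"""Kaplan-Meier / log-rank comparison of high- vs low-score patients.

Overall survival is compared at the 3-year, 5-year and unrestricted
horizons (administrative censoring at the horizon), plus the binary
within-horizon mortality odds ratio used in the horizon logistic models.
"""

import math

import numpy as np

from ppsn import (
    classify,
    contingency_2x2,
    derive_panel_cutoffs,
    derive_score_threshold,
    generate,
    horizon_binary_outcome,
    km_estimate,
    log_rank,
    odds_ratio_wald,
    paper_calibrated_config,
    restrict_horizon,
    score_cohort,
)
from ppsn.survival import YEARS_3, YEARS_5, SurvivalData

cohort = generate(paper_calibrated_config(seed=1))
death = [r.death for r in cohort]
cutoffs = derive_panel_cutoffs(cohort, death)
scores = score_cohort(cohort, cutoffs)
threshold = derive_score_threshold([s.score for s in scores], death)
classes = np.array([classify(s, threshold.threshold) for s in scores])

data = SurvivalData(
    time=np.array([r.os_days for r in cohort]),
    event=np.array(death, dtype=bool),
    group=classes,
)

for name, horizon in [("3-year", YEARS_3), ("5-year", YEARS_5), ("total", math.inf)]:
    restricted = restrict_horizon(data, horizon)
    lr = log_rank(restricted, ("low", "high"))
    km_low = km_estimate(restricted.subset(restricted.group == "low"))
    km_high = km_estimate(restricted.subset(restricted.group == "high"))
    t_show = min(horizon, YEARS_3)
    print(f"{name} OS: log-rank chi2={lr.chi2:.2f}, p={lr.p:.2g}; "
          f"S_low({t_show:.0f}d)={km_low.survival_at(t_show):.2f}, "
          f"S_high={km_high.survival_at(t_show):.2f}")
    out = horizon_binary_outcome(data, horizon)
    expo = classes[out.included] == "high"
    res = odds_ratio_wald(contingency_2x2(expo, out.event))
    print(f"  within-horizon mortality OR (high vs low): {res.or_point:.2f} "
          f"({res.ci_low:.2f}-{res.ci_high:.2f}), excluded={out.n_excluded}")
# Expect a clear separation: high-score patients die earlier, the log-rank
# p-value is typically far below 0.001 under the calibrated conditions.
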