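"""End-to-end analysis orchestration and the worked-example harness.

``run_full_analysis`` executes the whole procedure on one cohort: derive
the seven Youden cutoffs against mortality on each marker's complete
cases, score every patient, derive the high/low threshold of the score,
compute per-marker and composite odds ratios, run the horizon-restricted
(3-year / 5-year / total) logistic analyses, estimate Kaplan-Meier curves
and log-rank tests for OS and PFS split by score class, and compare TIL
counts between score classes when tissue data are present.

``reproduce_worked_examples`` is the desk-check harness: it reconstructs
the 2x2 counts behind each published summary row and recomputes every
derivable number, comparing under the truncate-to-two-decimals display
rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _tables
from .cohort import Cohort
from .inference import (
    ContingencyTable,
    OddsRatioResult,
    SeparationError,
    contingency_2x2,
    logistic_fit,
    odds_ratio_wald,
    rank_correlation,
    compare_groups,
)
from .roc import CutoffSpec, DiagnosticMetrics, truncate2
from .score import (
    PanelCutoffs,
    PpsnResult,
    ScoreThreshold,
    classify,
    derive_panel_cutoffs,
    derive_score_threshold,
    score_cohort,
)
from .survival import (
    YEARS_3,
    YEARS_5,
    KMCurve,
    LogRankResult,
    SurvivalData,
    horizon_binary_outcome,
    km_estimate,
    log_rank,
    restrict_horizon,
)

__all__ = ["AnalysisReport", "run_full_analysis", "reproduce_worked_examples"]

log = logging.getLogger("ppsn")

HORIZONS = {"3y": YEARS_3, "5y": YEARS_5, "total": math.inf}


@dataclass(frozen=True)
class MarkerRow:
    """One row of the per-marker cutoff table."""

    marker: str
    timepoint: str
    spec: CutoffSpec
    metrics: DiagnosticMetrics
    n_used: int
    univariate: OddsRatioResult | None


@dataclass(frozen=True)
class HorizonRow:
    """One horizon x predictor logistic association."""

    horizon: str
    predictor: str
    n_used: int
    n_excluded: int
    result: OddsRatioResult | None
    note: str = ""


@dataclass(frozen=True)
class KMPanel:
    endpoint: str  # "os" | "pfs"
    horizon: str
    curves: dict[str, KMCurve]
    logrank: LogRankResult


@dataclass(frozen=True)
class AnalysisReport:
    """Everything one cohort analysis produces, full precision throughout."""

    n: int
    cutoffs: PanelCutoffs
    marker_rows: list[MarkerRow]
    scores: list[PpsnResult]
    score_threshold: ScoreThreshold
    score_classes: list[str]
    multivariate: dict[str, OddsRatioResult] | None
    multivariate_note: str
    horizon_rows: list[HorizonRow]
    km_panels: list[KMPanel]
    tils: dict[str, dict] | None
    provenance: dict = field(default_factory=dict)

    def marker_table_rows(self) -> list[dict]:
        """Display-layer table (two-decimal truncated percentages)."""
        out = []
        for row in self.marker_rows:
            m = row.metrics
            out.append(
                {
                    "marker": row.marker,
                    "timepoint": row.timepoint,
                    "auc": round(row.spec.auc, 3),
                    "p": round(row.spec.auc_p, 3),
                    "cutoff": round(row.spec.cutoff, 2),
                    "sensitivity": round(m.sensitivity, 3),
                    "specificity": round(m.specificity, 3),
                    "ppv": None if m.ppv is None else truncate2(m.ppv),
                    "npv": None if m.npv is None else truncate2(m.npv),
                    "n": row.n_used,
                }
            )
        return out


def _marker_exposure(cohort: Cohort, spec: CutoffSpec) -> list[bool | None]:
    return [
        spec.is_abnormal(r.marker(spec.timepoint, spec.marker)) for r in cohort.records
    ]


def _survival_data(cohort: Cohort, endpoint: str, groups: Sequence[str]) -> SurvivalData:
    times, events, labels = [], [], []
    for r, g in zip(cohort.records, groups):
        if endpoint == "os":
            t, e = r.os_days, r.death
        else:
            t, e = r.pfs_days, (
                None if r.recurrence is None and r.death is None
                else bool(r.recurrence) or bool(r.death)
            )
            if t is None:
                t, e = r.os_days, r.death  # no progression info: fall back to OS
        if t is None or e is None or g is None:
            continue
        times.append(float(t))
        events.append(bool(e))
        labels.append(g)
    return SurvivalData(
        time=np.asarray(times), event=np.asarray(events, dtype=bool), group=np.asarray(labels)
    )


def run_full_analysis(
    cohort: Cohort,
    multivariate_predictors: Sequence[tuple[str, str]] = (
        ("pre", "lymphocyte_count"),
        ("post", "lymphocyte_count"),
    ),
) -> AnalysisReport:
    """Run every stage of the analysis on one cohort.

    Pure function of its inputs: repeated calls give identical reports.
    ``multivariate_predictors`` lists the (timepoint, marker) pairs entered
    jointly into the mortality logistic model; no automatic selection is
    performed.
    """
    death = [r.death for r in cohort.records]
    log.info("cohort: %d records", len(cohort))

    cutoffs = derive_panel_cutoffs(cohort, death)
    marker_rows: list[MarkerRow] = []
    for spec, met, n_used in zip(cutoffs.cutoffs, cutoffs.metrics, cutoffs.n_used):
        uni: OddsRatioResult | None
        try:
            uni = odds_ratio_wald(met.table)
        except ValueError:
            uni = None
        marker_rows.append(
            MarkerRow(
                marker=spec.marker,
                timepoint=spec.timepoint,
                spec=spec,
                metrics=met,
                n_used=n_used,
                univariate=uni,
            )
        )
        log.info("cutoff %s.%s: %.4g (n=%d)", spec.timepoint, spec.marker, spec.cutoff, n_used)

    scores = score_cohort(cohort, cutoffs)
    threshold = derive_score_threshold(
        [s.score for s in scores], [bool(d) for d in death]
    )
    classes = [classify(s, threshold.threshold) for s in scores]
    log.info("score threshold: %d (J=%.3f)", threshold.threshold, threshold.youden_j)

    # joint logistic model on the listed abnormal-marker indicators
    multivariate: dict[str, OddsRatioResult] | None = None
    multivariate_note = ""
    spec_by_key = {(c.timepoint, c.marker): c for c in cutoffs.cutoffs}
    design_cols, col_names, keep = [], [], None
    for tp, name in multivariate_predictors:
        expo = _marker_exposure(cohort, spec_by_key[(tp, name)])
        col = np.asarray([math.nan if e is None else float(e) for e in expo])
        design_cols.append(col)
        col_names.append(f"{tp}.{name}")
    if design_cols:
        X = np.column_stack(design_cols)
        y = np.asarray([math.nan if d is None else float(d) for d in death])
        keep = ~(np.isnan(X).any(axis=1) | np.isnan(y))
        try:
            fit = logistic_fit(
                np.column_stack([np.ones(int(keep.sum())), X[keep]]), y[keep]
            )
            ors = fit.odds_ratios()[1:]
            multivariate = dict(zip(col_names, ors))
        except (SeparationError, RuntimeError, ValueError) as exc:
            multivariate_note = f"multivariate fit unavailable: {exc}"
            log.warning("%s", multivariate_note)

    # horizon logistic analyses: FIGO IV, surgical outcome, high score
    predictors: dict[str, list[bool | None]] = {
        "figo_iv": [None if r.figo_stage is None else r.figo_stage == 4 for r in cohort.records],
        "surgical_others": [
            None if r.surgical_outcome is None else r.surgical_outcome == "others"
            for r in cohort.records
        ],
        "ppsn_high": [c == "high" for c in classes],
    }
    os_all = _survival_data(cohort, "os", ["all"] * len(cohort))
    horizon_rows: list[HorizonRow] = []
    for hname, hdays in HORIZONS.items():
        out = horizon_binary_outcome(os_all, hdays)
        for pname, expo in predictors.items():
            expo_arr = [e for e, m in zip(expo, out.included) if m]
            ev = list(out.event)
            try:
                table = contingency_2x2(expo_arr, ev)
                res = odds_ratio_wald(table)
                note = ""
            except ValueError as exc:
                res, note = None, str(exc)
            horizon_rows.append(
                HorizonRow(
                    horizon=hname,
                    predictor=pname,
                    n_used=int(out.included.sum()),
                    n_excluded=out.n_excluded,
                    result=res,
                    note=note,
                )
            )

    # KM / log-rank by score class, per endpoint and horizon
    km_panels: list[KMPanel] = []
    for endpoint in ("os", "pfs"):
        data = _survival_data(cohort, endpoint, classes)
        for hname, hdays in HORIZONS.items():
            restricted = restrict_horizon(data, hdays)
            curves = {
                lab: km_estimate(restricted.subset(restricted.group == lab))
                for lab in ("low", "high")
                if (restricted.group == lab).any()
            }
            if len(curves) == 2:
                lr = log_rank(restricted, ("low", "high"))
                km_panels.append(
                    KMPanel(endpoint=endpoint, horizon=hname, curves=curves, logrank=lr)
                )

    # tissue lymphocytes by score class
    tils_block: dict[str, dict] | None = None
    til_records = [
        (r, c) for r, c in zip(cohort.records, classes) if r.tils is not None
    ]
    if til_records:
        tils_block = {}
        for key in ("cd3_tils", "cd3_stils", "cd8_tils", "cd8_stils", "cd56_tils", "cd56_stils"):
            lo = [getattr(r.tils, key) for r, c in til_records if c == "low"]
            hi = [getattr(r.tils, key) for r, c in til_records if c == "high"]
            lo = [v for v in lo if v is not None]
            hi = [v for v in hi if v is not None]
            entry: dict = {
                "n_low": len(lo),
                "n_high": len(hi),
                "mean_low": float(np.mean(lo)) if lo else None,
                "mean_high": float(np.mean(hi)) if hi else None,
            }
            if len(lo) >= 1 and len(hi) >= 1:
                cmp_res = compare_groups(lo, hi)
                entry.update(p=cmp_res.p, test_used=cmp_res.test_used)
            tils_block[key] = entry
        # blood-tissue correlation for the intra-epithelial CD3/CD8 counts
        for key in ("cd3_tils", "cd8_tils"):
            pairs = [
                (r.marker("pre", "lymphocyte_count"), getattr(r.tils, key))
                for r, _ in til_records
            ]
            xs = [a for a, b in pairs if a is not None and b is not None]
            ys = [b for a, b in pairs if a is not None and b is not None]
            if len(xs) >= 4 and len(set(xs)) > 1 and len(set(ys)) > 1:
                rho, p = rank_correlation(xs, ys)
                tils_block[key]["lymphocyte_correlation"] = {"rho": rho, "p": p}
    else:
        log.info("no TIL data present; tissue block omitted")

    return AnalysisReport(
        n=len(cohort),
        cutoffs=cutoffs,
        marker_rows=marker_rows,
        scores=scores,
        score_threshold=threshold,
        score_classes=classes,
        multivariate=multivariate,
        multivariate_note=multivariate_note,
        horizon_rows=horizon_rows,
        km_panels=km_panels,
        tils=tils_block,
        provenance={"provenance": cohort.provenance, "n": len(cohort)},
    )


# ---------------------------------------------------------------------------
# Worked-example harness


def _check(name: str, expected: float, actual: float, tol: float = 0.0) -> dict:
    ok = abs(actual - expected) <= tol
    return {
        "target": name,
        "expected": expected,
        "actual": actual,
        "delta": actual - expected,
        "pass": bool(ok),
    }


def reproduce_worked_examples() -> list[dict]:
    """Recompute every published summary number that is derivable at desk.

    For each per-marker row the 2x2 counts are reconstructed from the
    printed sensitivity/specificity on the complete-case denominators; the
    harness then recomputes Se, Sp, PPV, NPV (truncated to the printed
    precision), the univariate cross-product odds ratio and its Wald CI,
    plus the FIGO stage-IV odds ratio from the cohort-table counts.
    Returns one pass/fail record per compared number.
    """
    checks: list[dict] = []
    for row in _tables.ROC_ROWS:
        tp, fp, fn, tn = _tables.reconstruct_counts(row)
        table = ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
        key = f"{row['timepoint']}.{row['marker']}"
        se = tp / (tp + fn)
        sp = tn / (tn + fp)
        checks.append(_check(f"{key}.sensitivity", row["sensitivity"], round(se, 3), 5e-4))
        checks.append(_check(f"{key}.specificity", row["specificity"], round(sp, 3), 5e-4))
        checks.append(_check(f"{key}.ppv", row["ppv"], truncate2(100.0 * tp / (tp + fp))))
        checks.append(_check(f"{key}.npv", row["npv"], truncate2(100.0 * tn / (tn + fn))))
        printed_or = _tables.UNIVARIATE_OR_ROWS[(row["timepoint"], row["marker"])]
        res = odds_ratio_wald(table)
        checks.append(_check(f"{key}.or", printed_or["or"], truncate2(res.or_point)))
        checks.append(_check(f"{key}.ci_low", printed_or["ci_low"], truncate2(res.ci_low)))
        checks.append(_check(f"{key}.ci_high", printed_or["ci_high"], truncate2(res.ci_high)))
    live_iv, dead_iv = _tables.FIGO_COUNTS[4]
    live_lo = sum(v[0] for k, v in _tables.FIGO_COUNTS.items() if k != 4)
    dead_lo = sum(v[1] for k, v in _tables.FIGO_COUNTS.items() if k != 4)
    figo_table = ContingencyTable(tp=dead_iv, fp=live_iv, fn=dead_lo, tn=live_lo)
    res = odds_ratio_wald(figo_table)
    checks.append(_check("figo_iv.or", _tables.FIGO_OR["or"], truncate2(res.or_point)))
    checks.append(_check("figo_iv.ci_low", _tables.FIGO_OR["ci_low"], truncate2(res.ci_low)))
    checks.append(_check("figo_iv.ci_high", _tables.FIGO_OR["ci_high"], truncate2(res.ci_high)))
    return checks
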