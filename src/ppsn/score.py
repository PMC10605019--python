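"""The PPSN composite score.

PPSN (Prognosis Predictive Score around NACT) counts how many of seven
peripheral-blood parameters sit on their abnormal side: pre-treatment
neutrophil %, lymphocyte % and lymphocyte count, and post-NACT
neutrophil %, lymphocyte %, lymphocyte count and platelet count.  Elevated
neutrophils and depressed lymphocytes/platelets are abnormal, so the score
runs 0 (all normal) to 7 (all abnormal).  Each marker's cutoff is the
Youden-optimal threshold of its ROC against overall mortality, derived on
that marker's complete cases; the high/low split of the score itself is
re-derived the same way on the score's own ROC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, PatientRecord
from .roc import (
    HIGH_ABNORMAL,
    LOW_ABNORMAL,
    CutoffSpec,
    DiagnosticMetrics,
    RocError,
    build_roc,
    diagnostic_metrics,
    youden_cutoff,
)

__all__ = [
    "PANEL_DEFINITION",
    "PanelCutoffs",
    "PpsnResult",
    "ScoreThreshold",
    "MissingScoreError",
    "derive_panel_cutoffs",
    "score_patient",
    "score_cohort",
    "derive_score_threshold",
    "classify",
]

#: The seven (timepoint, marker, abnormal direction) triples, in panel order.
PANEL_DEFINITION: tuple[tuple[str, str, str], ...] = (
    ("pre", "neutrophil_pct", HIGH_ABNORMAL),
    ("pre", "lymphocyte_pct", LOW_ABNORMAL),
    ("pre", "lymphocyte_count", LOW_ABNORMAL),
    ("post", "neutrophil_pct", HIGH_ABNORMAL),
    ("post", "lymphocyte_pct", LOW_ABNORMAL),
    ("post", "lymphocyte_count", LOW_ABNORMAL),
    ("post", "platelet_count", LOW_ABNORMAL),
)


class MissingScoreError(ValueError):
    """All seven markers missing: no score can be assigned."""


@dataclass(frozen=True)
class PanelCutoffs:
    """Exactly seven cutoffs, one per panel triple, plus per-marker metrics."""

    cutoffs: tuple[CutoffSpec, ...]
    metrics: tuple[DiagnosticMetrics, ...] | None = None
    n_used: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        triples = tuple((c.timepoint, c.marker, c.direction) for c in self.cutoffs)
        if triples != PANEL_DEFINITION:
            raise ValueError(
                "panel must contain exactly the seven defined "
                f"(timepoint, marker, direction) triples in order; got {triples}"
            )

    def __iter__(self):
        return iter(self.cutoffs)

    def __len__(self) -> int:
        return len(self.cutoffs)


@dataclass(frozen=True)
class PpsnResult:
    """Per-patient score with availability bookkeeping.

    ``score`` counts abnormal markers among those available; a missing
    marker contributes nothing and decrements ``n_markers_available``.
    ``high`` is ``score >= threshold`` once a threshold is attached.
    """

    patient_id: str
    score: int
    n_markers_available: int
    high: bool | None = None
    threshold: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.score <= self.n_markers_available <= 7:
            raise ValueError(
                f"score {self.score} / available {self.n_markers_available} out of range"
            )


@dataclass(frozen=True)
class ScoreThreshold:
    """Youden-optimal integer split of the score (high iff score >= threshold)."""

    threshold: int
    youden_j: float
    auc: float
    auc_p: float


def derive_panel_cutoffs(cohort: Cohort, outcome=None) -> PanelCutoffs:
    """Youden cutoffs for all seven markers against mortality.

    Each marker uses its own complete cases (records where that marker is
    present and the outcome defined).  ``outcome`` defaults to each
    record's death indicator.  A marker whose complete cases hold a single
    outcome class, or fewer than 2 per class, raises naming the marker.
    """
    if outcome is None:
        outcome = [r.death for r in cohort.records]
    outcome = list(outcome)
    if len(outcome) != len(cohort.records):
        raise ValueError("outcome length must match cohort size")
    specs: list[CutoffSpec] = []
    mets: list[DiagnosticMetrics] = []
    ns: list[int] = []
    for timepoint, marker, direction in PANEL_DEFINITION:
        vals, labs = [], []
        for r, ev in zip(cohort.records, outcome):
            v = r.marker(timepoint, marker)
            if v is not None and ev is not None:
                vals.append(float(v))
                labs.append(bool(ev))
        n_pos = sum(labs)
        n_neg = len(labs) - n_pos
        if min(n_pos, n_neg) < 2:
            raise RocError(
                f"marker {timepoint}.{marker}: need >= 2 complete cases per "
                f"outcome class, got {n_pos} events / {n_neg} non-events"
            )
        curve = build_roc(vals, labs, direction)
        spec = youden_cutoff(curve, marker=marker, timepoint=timepoint)
        specs.append(spec)
        mets.append(diagnostic_metrics(vals, labs, spec))
        ns.append(len(vals))
    return PanelCutoffs(cutoffs=tuple(specs), metrics=tuple(mets), n_used=tuple(ns))


def score_patient(record: PatientRecord, cutoffs: PanelCutoffs) -> PpsnResult:
    """Count abnormal markers for one patient.

    Missing markers are skipped (score unchanged, availability reduced);
    a patient with no marker at all cannot be scored.
    """
    score = 0
    available = 0
    for spec in cutoffs:
        flag = spec.is_abnormal(record.marker(spec.timepoint, spec.marker))
        if flag is None:
            continue
        available += 1
        score += int(flag)
    if available == 0:
        raise MissingScoreError(
            f"patient {record.patient_id}: all seven markers missing"
        )
    return PpsnResult(
        patient_id=record.patient_id, score=score, n_markers_available=available
    )


def score_cohort(cohort: Cohort, cutoffs: PanelCutoffs) -> list[PpsnResult]:
    return [score_patient(r, cutoffs) for r in cohort.records]


def derive_score_threshold(scores, outcome) -> ScoreThreshold:
    """Youden-optimal integer threshold of the score against an event.

    The score ROC is built high-abnormal; the midpoint cutoff it returns is
    reported as the smallest integer t with "high" iff score >= t.  A
    degenerate (single-valued) score distribution raises.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if np.unique(s).size == 1:
        raise ValueError("score distribution is degenerate; no threshold exists")
    curve = build_roc(s, y, HIGH_ABNORMAL)
    spec = youden_cutoff(curve, marker="ppsn", timepoint="score")
    return ScoreThreshold(
        threshold=int(np.ceil(spec.cutoff)),
        youden_j=spec.youden_j,
        auc=spec.auc,
        auc_p=spec.auc_p,
    )


def classify(result: PpsnResult, threshold: int) -> str:
    """``"high"`` iff the score reaches the threshold, else ``"low"``."""
    return "high" if result.score >= threshold else "low"
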