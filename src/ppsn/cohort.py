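"""Cohort data model and CSV I/O.

A cohort is an ordered collection of patient records, each holding
demographics, the peripheral-blood marker panel at two timepoints
(pre-treatment and post neoadjuvant chemotherapy), survival outcomes, and
optionally tumor-infiltrating-lymphocyte (TIL) counts.  Units are fixed by
the schema and never converted: lymphocyte counts are in hundreds per
microlitre (x10^2/uL), platelet counts in tens of thousands per microlitre
(x10^4/uL), percentages are fractions of white cells in [0, 100].

Missing values are retained per record and excluded per analysis
(complete-case per marker); nothing is imputed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "MarkerPanel",
    "TilPanel",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "EmptyCohortWarning",
    "read_cohort",
    "write_cohort",
    "complete_case_subset",
    "write_report",
    "COHORT_COLUMNS",
]

FIGO_STAGES = (2, 3, 4)
SUBTYPES = ("serous", "endometrioid", "clear_cell", "mucinous", "mixed", "other")
SURGICAL_OUTCOMES = ("complete", "others")

#: Canonical CSV column order.  Missing values are empty cells.
COHORT_COLUMNS = [
    "patient_id",
    "age",
    "bmi",
    "parity",
    "figo_stage",
    "subtype",
    "surgical_outcome",
    "days_first_treatment_to_ids",
    "pre_neutrophil_pct",
    "pre_lymphocyte_pct",
    "pre_lymphocyte_count",
    "pre_platelet_count",
    "post_neutrophil_pct",
    "post_lymphocyte_pct",
    "post_lymphocyte_count",
    "post_platelet_count",
    "death",
    "os_days",
    "recurrence",
    "pfs_days",
    "cd3_tils",
    "cd3_stils",
    "cd8_tils",
    "cd8_stils",
    "cd56_tils",
    "cd56_stils",
]


class CohortValidationError(ValueError):
    """Raised when a cohort file or record violates the schema."""


class EmptyCohortWarning(UserWarning):
    """Emitted when a complete-case subset comes back empty."""


@dataclass(frozen=True)
class MarkerPanel:
    """One timepoint's blood counts.

    ``neutrophil_pct`` and ``lymphocyte_pct`` are percentages of white
    cells; ``lymphocyte_count`` is x10^2/uL; ``platelet_count`` is
    x10^4/uL.  Any field may be missing (``None``).
    """

    neutrophil_pct: float | None = None
    lymphocyte_pct: float | None = None
    lymphocyte_count: float | None = None
    platelet_count: float | None = None

    def __post_init__(self) -> None:
        for name in ("neutrophil_pct", "lymphocyte_pct"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise CohortValidationError(f"{name}={v!r} outside [0, 100]")
        for name in ("lymphocyte_count", "platelet_count"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise CohortValidationError(f"{name}={v!r} negative")
        if (
            self.neutrophil_pct is not None
            and self.lymphocyte_pct is not None
            and self.neutrophil_pct + self.lymphocyte_pct > 100.0 + 1e-9
        ):
            raise CohortValidationError(
                "neutrophil_pct + lymphocyte_pct exceeds 100"
            )

    @property
    def empty(self) -> bool:
        return all(
            getattr(self, f.name) is None for f in dc_fields(self)
        )


@dataclass(frozen=True)
class TilPanel:
    """Tumor-infiltrating lymphocyte counts summed over 20 high-power fields.

    ``*_tils`` are intra-epithelial counts, ``*_stils`` stromal counts, for
    the CD3+, CD8+ and CD56+ phenotypes.
    """

    cd3_tils: float | None = None
    cd3_stils: float | None = None
    cd8_tils: float | None = None
    cd8_stils: float | None = None
    cd56_tils: float | None = None
    cd56_stils: float | None = None

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v is not None and v < 0:
                raise CohortValidationError(f"{f.name}={v!r} negative")

    @property
    def empty(self) -> bool:
        return all(getattr(self, f.name) is None for f in dc_fields(self))


@dataclass(frozen=True)
class PatientRecord:
    """One subject: demographics, marker panels, outcomes.

    ``death`` and ``recurrence`` are event indicators; the associated times
    are ``os_days`` (time to death or last follow-up) and ``pfs_days``
    (time to recurrence-or-death or last follow-up), both measured from the
    start of first treatment.
    """

    patient_id: str
    age: float | None = None
    bmi: float | None = None
    parity: int | None = None
    figo_stage: int | None = None
    subtype: str | None = None
    surgical_outcome: str | None = None
    days_first_treatment_to_ids: float | None = None
    pre: MarkerPanel | None = None
    post: MarkerPanel | None = None
    death: bool | None = None
    os_days: float | None = None
    recurrence: bool | None = None
    pfs_days: float | None = None
    tils: TilPanel | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("patient_id must be non-empty")
        if self.figo_stage is not None and self.figo_stage not in FIGO_STAGES:
            raise CohortValidationError(
                f"figo_stage={self.figo_stage!r} not in {FIGO_STAGES}"
            )
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise CohortValidationError(f"unknown subtype {self.subtype!r}")
        if (
            self.surgical_outcome is not None
            and self.surgical_outcome not in SURGICAL_OUTCOMES
        ):
            raise CohortValidationError(
                f"unknown surgical_outcome {self.surgical_outcome!r}"
            )
        if self.parity is not None and self.parity < 0:
            raise CohortValidationError("parity must be non-negative")
        for name in ("os_days", "pfs_days"):
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise CohortValidationError(f"{name}={v!r} must be finite and > 0")
        if (
            self.os_days is not None
            and self.pfs_days is not None
            and self.os_days + 1e-9 < self.pfs_days
        ):
            raise CohortValidationError(
                f"os_days={self.os_days} < pfs_days={self.pfs_days}"
            )
        for name in ("death", "recurrence"):
            v = getattr(self, name)
            if v is not None and not isinstance(v, bool):
                raise CohortValidationError(f"{name} must be boolean, got {v!r}")

    def marker(self, timepoint: str, name: str) -> float | None:
        """Return one marker value (``None`` when the panel or cell is missing)."""
        panel = getattr(self, timepoint)
        if panel is None:
            return None
        return getattr(panel, name)


@dataclass(frozen=True)
class Cohort:
    """Ordered, uniquely-identified collection of patient records."""

    records: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise CohortValidationError("cohort must be non-empty")
        seen: set[str] = set()
        for r in self.records:
            if r.patient_id in seen:
                raise CohortValidationError(
                    f"duplicated patient_id {r.patient_id!r}"
                )
            seen.add(r.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def marker_values(self, timepoint: str, name: str) -> list[float | None]:
        return [r.marker(timepoint, name) for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical column layout (one row per patient)."""
        rows = [_record_to_row(r) for r in self.records]
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)


# ---------------------------------------------------------------------------
# CSV round-trip

_BOOL_COLS = ("death", "recurrence")
_INT_COLS = ("parity", "figo_stage")
_STR_COLS = ("patient_id", "subtype", "surgical_outcome")


def _record_to_row(r: PatientRecord) -> dict[str, object]:
    row: dict[str, object] = {
        "patient_id": r.patient_id,
        "age": r.age,
        "bmi": r.bmi,
        "parity": r.parity,
        "figo_stage": r.figo_stage,
        "subtype": r.subtype,
        "surgical_outcome": r.surgical_outcome,
        "days_first_treatment_to_ids": r.days_first_treatment_to_ids,
        "death": None if r.death is None else int(r.death),
        "os_days": r.os_days,
        "recurrence": None if r.recurrence is None else int(r.recurrence),
        "pfs_days": r.pfs_days,
    }
    for tp in ("pre", "post"):
        panel = getattr(r, tp)
        for m in ("neutrophil_pct", "lymphocyte_pct", "lymphocyte_count", "platelet_count"):
            row[f"{tp}_{m}"] = None if panel is None else getattr(panel, m)
    tils = r.tils
    for m in ("cd3_tils", "cd3_stils", "cd8_tils", "cd8_stils", "cd56_tils", "cd56_stils"):
        row[m] = None if tils is None else getattr(tils, m)
    return row


def _cell(raw: object, row_idx: int, col: str, strict: bool) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, str):
        raw = raw.strip()
        if raw == "":
            return None
        try:
            return float(raw)
        except ValueError:
            if strict:
                raise CohortValidationError(
                    f"non-numeric value {raw!r} in column {col!r}, row {row_idx}"
                ) from None
            return None
    return float(raw)  # type: ignore[arg-type]


def _row_to_record(row: Mapping[str, object], idx: int, strict: bool) -> PatientRecord:
    def num(col: str) -> float | None:
        return _cell(row.get(col), idx, col, strict)

    def as_int(col: str) -> int | None:
        v = num(col)
        return None if v is None else int(round(v))

    def as_bool(col: str) -> bool | None:
        v = num(col)
        return None if v is None else bool(int(round(v)))

    def as_str(col: str) -> str | None:
        raw = row.get(col)
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return None
        s = str(raw).strip()
        return s or None

    panels: dict[str, MarkerPanel | None] = {}
    for tp in ("pre", "post"):
        panel = MarkerPanel(
            neutrophil_pct=num(f"{tp}_neutrophil_pct"),
            lymphocyte_pct=num(f"{tp}_lymphocyte_pct"),
            lymphocyte_count=num(f"{tp}_lymphocyte_count"),
            platelet_count=num(f"{tp}_platelet_count"),
        )
        panels[tp] = None if panel.empty else panel
    tils = TilPanel(
        cd3_tils=num("cd3_tils"),
        cd3_stils=num("cd3_stils"),
        cd8_tils=num("cd8_tils"),
        cd8_stils=num("cd8_stils"),
        cd56_tils=num("cd56_tils"),
        cd56_stils=num("cd56_stils"),
    )
    pid = as_str("patient_id")
    if pid is None:
        raise CohortValidationError(f"missing patient_id in row {idx}")
    return PatientRecord(
        patient_id=pid,
        age=num("age"),
        bmi=num("bmi"),
        parity=as_int("parity"),
        figo_stage=as_int("figo_stage"),
        subtype=as_str("subtype"),
        surgical_outcome=as_str("surgical_outcome"),
        days_first_treatment_to_ids=num("days_first_treatment_to_ids"),
        pre=panels["pre"],
        post=panels["post"],
        death=as_bool("death"),
        os_days=num("os_days"),
        recurrence=as_bool("recurrence"),
        pfs_days=num("pfs_days"),
        tils=None if tils.empty else tils,
    )


def read_cohort(path: str | Path, strict: bool = True) -> Cohort:
    """Read a cohort CSV.

    The header must match the documented schema exactly.  Empty cells become
    missing values, never zeros.  In strict mode a non-numeric cell in a
    numeric column raises :class:`CohortValidationError` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != COHORT_COLUMNS:
        raise CohortValidationError(
            f"header mismatch in {path.name}: expected {COHORT_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    records = [
        _row_to_record(row, i, strict)
        for i, row in enumerate(df.to_dict(orient="records"))
    ]
    return Cohort(records=tuple(records), provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the canonical CSV (UTF-8, comma-separated, empty cell = missing)."""
    df = cohort.to_frame()
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Complete-case subsetting

#: Shorthand field names accepted by :func:`complete_case_subset` in addition
#: to plain record attributes and ``timepoint.marker`` paths.
_PANEL_SHORTHAND = {
    "pre": ("pre_neutrophil_pct", "pre_lymphocyte_pct", "pre_lymphocyte_count", "pre_platelet_count"),
    "post": ("post_neutrophil_pct", "post_lymphocyte_pct", "post_lymphocyte_count", "post_platelet_count"),
}


def _field_present(r: PatientRecord, field: str) -> bool:
    if field in _PANEL_SHORTHAND:
        panel = getattr(r, field)
        return panel is not None and not any(
            getattr(panel, m) is None
            for m in ("neutrophil_pct", "lymphocyte_pct", "lymphocyte_count", "platelet_count")
        )
    if field == "tils":
        return r.tils is not None and not r.tils.empty
    if "." in field:
        tp, marker = field.split(".", 1)
        if tp not in ("pre", "post"):
            raise KeyError(f"unknown timepoint in field {field!r}")
        return r.marker(tp, marker) is not None
    if not any(f.name == field for f in dc_fields(PatientRecord)):
        raise KeyError(f"unknown field {field!r}")
    return getattr(r, field) is not None


def complete_case_subset(cohort: Cohort, required_fields: Sequence[str]) -> Cohort:
    """Records with every required field present, original order preserved.

    Field names are record attributes (``"death"``), dotted marker paths
    (``"pre.lymphocyte_count"``), or the shorthands ``"pre"`` / ``"post"``
    (full panel) and ``"tils"``.  Idempotent, and monotone in the field
    list: adding requirements never grows the subset.
    """
    kept = tuple(
        r for r in cohort.records
        if all(_field_present(r, f) for f in required_fields)
    )
    if not kept:
        warnings.warn(
            f"complete-case subset on {list(required_fields)} is empty",
            EmptyCohortWarning,
            stacklevel=2,
        )
        return _EmptyCohort(records=(), provenance=cohort.provenance)
    return Cohort(records=kept, provenance=cohort.provenance)


class _EmptyCohort(Cohort):
    """Zero-record cohort returned (with a warning) by an empty subset."""

    def __post_init__(self) -> None:  # uniqueness holds vacuously
        pass


# ---------------------------------------------------------------------------
# Report serialization


def _jsonify(obj: object) -> object:
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {
            f.name: _jsonify(getattr(obj, f.name))
            for f in dc_fields(obj)  # type: ignore[arg-type]
        }
    if isinstance(obj, float) and not math.isfinite(obj):
        return None if math.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        try:
            return obj.item()  # numpy scalar
        except Exception:
            pass
    return obj


def write_report(
    results: object,
    path: str | Path,
    format: str = "json",
) -> None:
    """Serialize analysis outputs deterministically.

    ``json`` accepts any nesting of mappings, sequences and dataclasses;
    ``tsv`` requires a sequence of flat mappings (rows).  Floats are written
    at full ``repr`` precision so the round trip is bit-stable; display
    rounding is a presentation concern handled by callers.
    """
    path = Path(path)
    if format == "json":
        payload = json.dumps(_jsonify(results), indent=2, sort_keys=True)
        path.write_text(payload + "\n", encoding="utf-8")
    elif format == "tsv":
        rows = [_jsonify(r) for r in results]  # type: ignore[union-attr]
        if rows and not all(isinstance(r, dict) for r in rows):
            raise TypeError("tsv format requires a sequence of mappings")
        cols: list[str] = []
        for r in rows:
            for k in r:  # type: ignore[union-attr]
                if k not in cols:
                    cols.append(k)
        lines = ["\t".join(cols)]
        for r in rows:
            lines.append(
                "\t".join(
                    "" if r.get(c) is None else repr(r.get(c))  # type: ignore[union-attr]
                    if isinstance(r.get(c), float) else str(r.get(c))  # type: ignore[union-attr]
                    for c in cols
                )
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")
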