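"""Cohort file I/O, report writing and run configuration.

The cohort CSV schema (header required, UTF-8) is one row per patient:

``patient_id, age, bmi, tpsa, dia_transverse, dia_ap, dia_cc,
lesion_diameter, pirads, lesion_side, lesion_level, lesion_zone,
core_1..core_N (0/1), isup_1..isup_N (integer, 0 = benign)``

with N equal to the core count of the template in use (12 or 13).  The
``isup_*`` columns are optional as a group.  Percent-valued statistics
are stored internally as proportions; formatting to two decimals
(round half up) happens only at the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .drs import CovariateVector
from .errors import CohortParseError, ValidationError
from .evaluation import CoreOutcomes
from .geometry import CoreLayout, LesionLocation

__all__ = [
    "PatientRecord",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "report_frame",
    "write_report",
    "round_half_up",
]

_BASE_COLUMNS = (
    "patient_id", "age", "bmi", "tpsa", "dia_transverse", "dia_ap", "dia_cc",
    "lesion_diameter", "pirads", "lesion_side", "lesion_level", "lesion_zone",
)

#: Table-2-style evaluation report columns.
REPORT_COLUMNS = (
    "layer", "k", "tp", "fn", "tn", "fp",
    "sensitivity_pct", "npv_pct", "accuracy_pct",
    "auc", "auc_lo", "auc_hi", "mcnemar_p",
)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: covariates, lesion location and per-core pathology."""

    patient_id: str
    covariates: CovariateVector
    lesion: LesionLocation
    outcomes: CoreOutcomes

    @property
    def reference_positive(self) -> bool:
        """Reference-standard status: any template core malignant."""
        return any(self.outcomes.positive)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration with validated enumerated fields."""

    layout: str = "changhai_12"
    ci_method: str = "hanley_mcneil"
    grade_threshold: int = 1
    quantile_rule: str = "linear"
    seed: int = 0
    verbosity: str = "info"

    _ALLOWED = {
        "layout": ("changhai_12", "fujian_13"),
        "ci_method": ("hanley_mcneil", "wald_halfsum"),
        "quantile_rule": ("linear",),
        "verbosity": ("quiet", "info", "debug"),
    }

    def __post_init__(self):
        for name, allowed in self._ALLOWED.items():
            if getattr(self, name) not in allowed:
                raise ValidationError(f"{name} must be one of {allowed}, got {getattr(self, name)!r}")
        if self.grade_threshold not in (1, 2, 3, 4, 5):
            raise ValidationError(f"grade_threshold must be in 1..5, got {self.grade_threshold!r}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as used for percent columns."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def read_cohort(path, layout: CoreLayout) -> list:
    """Read and validate a cohort CSV against a core template.

    Row-level problems are collected with their line numbers and raised
    together as a single :class:`CohortParseError`.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    core_cols = [c for c in df.columns if c.startswith("core_")]
    isup_cols = [c for c in df.columns if c.startswith("isup_")]
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError([f"missing column(s): {', '.join(missing)}"])
    expected_cores = [f"core_{i}" for i in range(1, layout.n + 1)]
    if sorted(core_cols, key=lambda c: int(c.split("_")[1])) != expected_cores:
        raise CohortParseError(
            [f"found {len(core_cols)} core columns but layout {layout.name!r} has {layout.n} cores"]
        )
    expected_isup = [f"isup_{i}" for i in range(1, layout.n + 1)]
    has_isup = bool(isup_cols)
    if has_isup and sorted(isup_cols, key=lambda c: int(c.split("_")[1])) != expected_isup:
        raise CohortParseError([f"isup columns must be isup_1..isup_{layout.n} or absent"])

    records, errors = [], []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            cov = CovariateVector(
                age=float(row["age"]), bmi=float(row["bmi"]), tpsa=float(row["tpsa"]),
                transverse_diameter=float(row["dia_transverse"]),
                anteroposterior_diameter=float(row["dia_ap"]),
                cephalocaudal_diameter=float(row["dia_cc"]),
                lesion_longest_diameter=float(row["lesion_diameter"]),
                pirads=int(row["pirads"]),
            ).validate()
            lesion = LesionLocation(
                side=str(row["lesion_side"]), level=str(row["lesion_level"]), zone=str(row["lesion_zone"]),
            )
            flags = [int(row[c]) for c in expected_cores]
            if any(f not in (0, 1) for f in flags):
                raise ValidationError("core flags must be 0/1")
            isup = [int(row[c]) for c in expected_isup] if has_isup else None
            outcomes = CoreOutcomes(positive=tuple(flags), isup=tuple(isup) if isup else None)
            records.append(PatientRecord(
                patient_id=str(row["patient_id"]), covariates=cov, lesion=lesion, outcomes=outcomes,
            ))
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise CohortParseError(errors)
    return records


def cohort_to_frame(records, layout: CoreLayout) -> pd.DataFrame:
    """Tabulate patient records into the cohort CSV schema."""
    rows = []
    for rec in records:
        cov = rec.covariates
        row = {
            "patient_id": rec.patient_id,
            "age": cov.age, "bmi": cov.bmi, "tpsa": cov.tpsa,
            "dia_transverse": cov.transverse_diameter,
            "dia_ap": cov.anteroposterior_diameter,
            "dia_cc": cov.cephalocaudal_diameter,
            "lesion_diameter": cov.lesion_longest_diameter,
            "pirads": cov.pirads,
            "lesion_side": rec.lesion.side, "lesion_level": rec.lesion.level,
            "lesion_zone": rec.lesion.zone,
        }
        for i in range(layout.n):
            row[f"core_{i + 1}"] = int(rec.outcomes.positive[i])
        isup = rec.outcomes.isup or tuple(int(p) for p in rec.outcomes.positive)
        for i in range(layout.n):
            row[f"isup_{i + 1}"] = int(isup[i])
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records, path, layout: CoreLayout) -> None:
    cohort_to_frame(records, layout).to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def report_frame(series_by_layer: dict) -> pd.DataFrame:
    """Format per-layer metric series as a Table-2-style report.

    ``series_by_layer`` maps layer index to a list of
    :class:`~biopsyreduce.evaluation.SchemeMetrics`.  Percent columns
    are rounded half-up to two decimals, AUC columns to three.
    """
    rows = []
    for layer in sorted(series_by_layer):
        for m in series_by_layer[layer]:
            rows.append({
                "layer": layer, "k": m.k,
                "tp": m.table.tp, "fn": m.table.fn, "tn": m.table.tn, "fp": m.table.fp,
                "sensitivity_pct": round_half_up(100.0 * m.sensitivity, 2),
                "npv_pct": round_half_up(100.0 * m.npv, 2),
                "accuracy_pct": round_half_up(100.0 * m.accuracy, 2),
                "auc": round_half_up(m.auc, 3),
                "auc_lo": round_half_up(m.auc_ci[0], 3) if m.auc_ci else np.nan,
                "auc_hi": round_half_up(m.auc_ci[1], 3) if m.auc_ci else np.nan,
                "mcnemar_p": round_half_up(m.mcnemar_p, 4) if m.mcnemar_p is not None else np.nan,
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(obj, path, fmt: str = "csv") -> None:
    """Write a report object byte-stably (sorted keys, fixed formats).

    ``obj`` may be a DataFrame, a mapping/dataclass with ``to_dict``, or
    any JSON-serializable structure.
    """
    if fmt not in ("csv", "json"):
        raise ValidationError(f"format must be 'csv' or 'json', got {fmt!r}")
    try:
        if fmt == "csv":
            if not isinstance(obj, pd.DataFrame):
                obj = pd.DataFrame(obj)
            obj.to_csv(path, index=False, float_format="%.4f", lineterminator="\n")
        else:
            payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")
    except OSError:
        raise
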