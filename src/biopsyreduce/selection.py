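"""Core-number selection, external validation and per-patient recommendation.

The selection rule is non-inferiority by AUC confidence bound: within
each risk layer, the chosen core count is the smallest k whose
two-sided 95% CI lower bound for the AUC (versus the 12-core reference)
is at least 0.95; if no reduced scheme qualifies, the full 12-core
template is kept.  A plan built on a training cohort is applied to an
external cohort with the *training* cutpoints, never re-quantiled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drs import (
    PUBLISHED,
    CovariateVector,
    DRSCoefficients,
    RiskStratification,
    assign_layer,
    compute_drs,
    make_strata,
)
from .errors import EligibilityError, ValidationError
from .evaluation import detect_at_k, evaluate_schemes
from .geometry import CoreLayout, LesionLocation, get_layout, rank_cores
from .io import report_frame

__all__ = [
    "LayerPlan",
    "ValidationReport",
    "Recommendation",
    "select_core_number",
    "build_plan",
    "external_validate",
    "recommend",
]

AUC_LOWER_BOUND = 0.95


def select_core_number(series, lower_bound: float = AUC_LOWER_BOUND) -> int:
    """Smallest available k whose AUC CI lower bound reaches ``lower_bound``.

    ``series`` is a list of :class:`~biopsyreduce.evaluation.SchemeMetrics`
    ordered by k (gaps allowed).  Falls back to 12 when no evaluated
    scheme qualifies.
    """
    series = sorted(series, key=lambda m: m.k)
    if not series:
        raise ValidationError("metric series is empty")
    for m in series:
        if m.auc_ci is None:
            raise ValidationError(f"scheme k={m.k} has no confidence interval attached")
        if m.auc_ci[0] >= lower_bound:
            return m.k
    return 12


@dataclass(frozen=True)
class LayerPlan:
    """Training strata plus the selected core count per layer.

    ``core_counts`` holds one entry per layer (1..5); ``None`` marks a
    layer whose selection was skipped (no reference-positive patients).
    The CI method and grade threshold used for selection are recorded
    so validation and recommendation reproduce the exact basis.
    """

    strata: RiskStratification
    core_counts: tuple
    layout_name: str
    coefficients: DRSCoefficients
    ci_method: str = "hanley_mcneil"
    grade_threshold: int = 1

    def __post_init__(self):
        counts = tuple(None if k is None else int(k) for k in self.core_counts)
        object.__setattr__(self, "core_counts", counts)
        if len(counts) != 5:
            raise ValidationError(f"expected 5 per-layer core counts, got {len(counts)}")
        for k in counts:
            if k is not None and not 1 <= k <= 12:
                raise ValidationError(f"core count {k} outside 1..12")

    def k_for_layer(self, layer: int) -> int:
        if not 1 <= layer <= 5:
            raise ValidationError(f"layer must be in 1..5, got {layer}")
        k = self.core_counts[layer - 1]
        if k is None:
            raise ValidationError(f"plan has no core count for layer {layer} (selection was skipped)")
        return k

    def to_dict(self) -> dict:
        return {
            "strata": self.strata.to_dict(),
            "core_counts": list(self.core_counts),
            "layout_name": self.layout_name,
            "coefficients": self.coefficients.to_dict(),
            "ci_method": self.ci_method,
            "grade_threshold": self.grade_threshold,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LayerPlan":
        return cls(
            strata=RiskStratification.from_dict(payload["strata"]),
            core_counts=tuple(payload["core_counts"]),
            layout_name=payload["layout_name"],
            coefficients=DRSCoefficients.from_dict(payload["coefficients"]),
            ci_method=payload.get("ci_method", "hanley_mcneil"),
            grade_threshold=int(payload.get("grade_threshold", 1)),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "LayerPlan":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _ranking_for(record, layout: CoreLayout, cache: dict) -> list:
    """Lesion-distance ranking over the standard (non-midline) cores."""
    loc = record.lesion
    key = loc.coords if loc.coords is not None else (loc.side, loc.level, loc.zone)
    if key not in cache:
        full = rank_cores(loc, layout)
        standard = set(layout.standard_core_ids)
        cache[key] = [cid for cid in full if cid in standard]
    return cache[key]


def build_plan(cohort, coef: DRSCoefficients = PUBLISHED, layout: CoreLayout = None,
               grade_threshold: int = 1, ci_method: str = "hanley_mcneil"):
    """Compose the whole training pipeline into a reproducible plan.

    Scores the cohort, builds quintile strata, ranks cores per lesion,
    evaluates every k-core scheme per layer, and applies the selection
    rule.  Returns ``(plan, report)`` where ``report`` is the
    Table-2-style DataFrame over all layers.  Layers without
    reference-positive patients are skipped with a warning.
    """
    cohort = list(cohort)
    if layout is None:
        layout = get_layout("changhai_12")
    if len(layout.standard_core_ids) != 12:
        raise ValidationError(f"layout {layout.name!r} must provide 12 standard cores")
    if layout.n > len(layout.standard_core_ids):
        warnings.warn(
            f"layout {layout.name!r}: midline core(s) are excluded from the "
            "12-core reference and from reduced schemes",
            stacklevel=2,
        )
    scores = [compute_drs(rec.covariates, coef) for rec in cohort]
    strata = make_strata(scores)
    layers = [assign_layer(s, strata) for s in scores]

    cache = {}
    series_by_layer = {}
    core_counts = []
    for layer in range(1, 6):
        members = [rec for rec, lay in zip(cohort, layers) if lay == layer]
        patients = [(rec.outcomes, _ranking_for(rec, layout, cache)) for rec in members]
        n_pos = sum(1 for rec in members if rec.reference_positive)
        if not members or n_pos == 0:
            warnings.warn(f"layer {layer}: no reference-positive patients; selection skipped", stacklevel=2)
            core_counts.append(None)
            series_by_layer[layer] = []
            continue
        series = evaluate_schemes(patients, grade_threshold=grade_threshold, ci_method=ci_method)
        series_by_layer[layer] = series
        core_counts.append(select_core_number(series))

    plan = LayerPlan(
        strata=strata, core_counts=tuple(core_counts), layout_name=layout.name,
        coefficients=coef, ci_method=ci_method, grade_threshold=grade_threshold,
    )
    return plan, report_frame(series_by_layer)


@dataclass(frozen=True)
class ValidationReport:
    """Per-layer external validation of a plan on reference-positive patients.

    ``accuracy_isup1`` is the detected fraction at the layer's reduced
    core count.  ``accuracy_isup2`` counts a missed patient against the
    scheme only when the missed cancer is clinically significant
    (patient-level maximum ISUP grade group >= 2), mirroring the
    csPCa-aware reading of the validation table; patients without
    per-core grades are treated as significant when missed.
    """

    rows: tuple  # of dicts: layer, k, n, detected, accuracy_isup1, accuracy_isup2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows),
            columns=["layer", "k", "n", "detected", "accuracy_isup1", "accuracy_isup2"],
        )

    def to_dict(self) -> dict:
        return {"rows": [dict(r) for r in self.rows]}


def external_validate(cohort, plan: LayerPlan, coef: DRSCoefficients = None,
                      layout: CoreLayout = None) -> ValidationReport:
    """Apply a trained plan to an external all-positive cohort.

    Patients are stratified with the training cutpoints; each layer's
    detection rate at its selected core count is reported at both grade
    readings.  Empty layers appear with n = 0 rather than being dropped.
    """
    cohort = list(cohort)
    if coef is None:
        coef = plan.coefficients
    if layout is None:
        layout = get_layout(plan.layout_name)
    for rec in cohort:
        if not rec.reference_positive:
            raise ValidationError(f"patient {rec.patient_id!r} is reference-negative; "
                                  "external validation expects biopsy-positive patients")
    cache = {}
    by_layer = {layer: [] for layer in range(1, 6)}
    for rec in cohort:
        layer = assign_layer(compute_drs(rec.covariates, coef), plan.strata)
        by_layer[layer].append(rec)

    rows = []
    for layer in range(1, 6):
        members = by_layer[layer]
        if not members:
            rows.append({"layer": layer, "k": plan.core_counts[layer - 1],
                         "n": 0, "detected": 0,
                         "accuracy_isup1": np.nan, "accuracy_isup2": np.nan})
            continue
        k = plan.k_for_layer(layer)
        detected = 0
        significant_misses = 0
        for rec in members:
            ranking = _ranking_for(rec, layout, cache)
            if detect_at_k(rec.outcomes, ranking, k, grade_threshold=1):
                detected += 1
            elif rec.outcomes.max_isup >= 2 or rec.outcomes.isup is None:
                significant_misses += 1
        n = len(members)
        rows.append({
            "layer": layer, "k": k, "n": n, "detected": detected,
            "accuracy_isup1": detected / n,
            "accuracy_isup2": (n - significant_misses) / n,
        })
    return ValidationReport(rows=tuple(rows))


@dataclass(frozen=True)
class Recommendation:
    """Output of the per-patient recommender (the website logic)."""

    drs: float
    layer: int
    k: int
    core_ids: tuple


def recommend(cov: CovariateVector, loc: LesionLocation, plan: LayerPlan,
              coef: DRSCoefficients = None, layout: CoreLayout = None) -> Recommendation:
    """Individualized core count and core locations for one patient.

    Computes the DRS, assigns the risk layer under the plan's training
    cutpoints, and returns the layer's selected core count together
    with the k template cores closest to the lesion.  Patients with
    PI-RADS < 3 are refused (model inclusion criterion).
    """
    if cov.pirads < 3:
        raise EligibilityError(
            f"PI-RADS {cov.pirads} is below the model's inclusion criterion (PI-RADS >= 3)"
        )
    if coef is None:
        coef = plan.coefficients
    if layout is None:
        layout = get_layout(plan.layout_name)
    drs = compute_drs(cov, coef)
    layer = assign_layer(drs, plan.strata)
    k = plan.k_for_layer(layer)
    full = rank_cores(loc, layout)
    standard = set(layout.standard_core_ids)
    ranking = [cid for cid in full if cid in standard]
    return Recommendation(drs=drs, layer=layer, k=k, core_ids=tuple(ranking[:k]))
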