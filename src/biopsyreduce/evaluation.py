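"""Per-scheme diagnostic evaluation against the 12-core reference.

A reduced k-core scheme is positive when any of the k cores closest to
the lesion contains cancer at or above a grade threshold (ISUP grade
group >= 1 for any cancer, >= 2 for clinically significant cancer).
Because the k-core set is a prefix of the ranked template, a reduced
scheme can never be positive when the full reference is negative:
false positives are structurally zero and specificity is exactly 1, so
the single-threshold AUC reduces to (1 + sensitivity) / 2.

Confidence intervals for the AUC use the Hanley-McNeil standard error
by default; paired detection rates are compared with an exact two-sided
McNemar (binomial) test, falling back to the continuity-corrected
chi-square when the discordant count exceeds 25.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "CoreOutcomes",
    "ContingencyTable",
    "SchemeMetrics",
    "detect_at_k",
    "tabulate_scheme",
    "metrics_from_table",
    "auc_ci",
    "mcnemar_exact",
    "evaluate_schemes",
]

CI_METHODS = ("hanley_mcneil", "wald_halfsum")


@dataclass(frozen=True)
class CoreOutcomes:
    """Per-core pathology of one patient, aligned with a core template.

    ``positive[i]`` flags malignancy in core ``i + 1``; ``isup`` holds
    the matching ISUP grade groups (0 = benign) when grading is
    available.
    """

    positive: tuple
    isup: tuple = None

    def __post_init__(self):
        object.__setattr__(self, "positive", tuple(bool(p) for p in self.positive))
        if self.isup is not None:
            isup = tuple(int(g) for g in self.isup)
            object.__setattr__(self, "isup", isup)
            if len(isup) != len(self.positive):
                raise ValidationError("isup length must match core count")
            for i, (pos, grade) in enumerate(zip(self.positive, isup)):
                if pos != (grade > 0) or grade < 0 or grade > 5:
                    raise ValidationError(
                        f"core {i + 1}: ISUP grade {grade} inconsistent with malignancy flag {pos}"
                    )

    @property
    def n_cores(self) -> int:
        return len(self.positive)

    @property
    def max_isup(self) -> int:
        """Highest grade over all cores (0 when benign or ungraded)."""
        if self.isup is None:
            return 1 if any(self.positive) else 0
        return max(self.isup, default=0)


@dataclass(frozen=True)
class ContingencyTable:
    """Patient counts of reduced-scheme result x 12-core reference result."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class SchemeMetrics:
    """Derived statistics of one k-core scheme versus the reference."""

    k: int
    table: ContingencyTable
    sensitivity: float
    npv: float
    accuracy: float
    specificity: float
    auc: float
    auc_ci: tuple = None
    mcnemar_p: float = None


def detect_at_k(outcomes: CoreOutcomes, ranking, k: int, grade_threshold: int = 1) -> bool:
    """True iff any of the first k ranked cores reaches ``grade_threshold``."""
    ranking = list(ranking)
    if not 1 <= k <= len(ranking):
        raise ValidationError(f"k must be in 1..{len(ranking)}, got {k}")
    if grade_threshold < 1:
        raise ValidationError(f"grade_threshold must be >= 1, got {grade_threshold}")
    if grade_threshold > 1 and outcomes.isup is None:
        raise ValidationError("grade_threshold > 1 requires per-core ISUP grades")
    for core_id in ranking[:k]:
        if grade_threshold == 1:
            if outcomes.positive[core_id - 1]:
                return True
        elif outcomes.isup[core_id - 1] >= grade_threshold:
            return True
    return False


def tabulate_scheme(patients, k: int, grade_threshold: int = 1) -> ContingencyTable:
    """2x2 table of the k-core scheme against the full-ranking reference.

    ``patients`` is a sequence of ``(CoreOutcomes, ranking)`` pairs.
    The reference standard is detection over the complete ranking at
    ISUP >= 1, regardless of ``grade_threshold``.
    """
    patients = list(patients)
    if not patients:
        raise ValidationError("patient list is empty")
    tp = fn = tn = fp = 0
    for outcomes, ranking in patients:
        reference = detect_at_k(outcomes, ranking, len(list(ranking)), grade_threshold=1)
        reduced = detect_at_k(outcomes, ranking, k, grade_threshold=grade_threshold)
        if reference and reduced:
            tp += 1
        elif reference:
            fn += 1
        elif reduced:
            fp += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fn=fn, tn=tn, fp=fp)


def metrics_from_table(table: ContingencyTable, k: int = 0) -> SchemeMetrics:
    """Sensitivity, NPV, accuracy and single-threshold AUC from a 2x2 table."""
    if table.n_pos < 1:
        raise ValidationError("sensitivity undefined: no reference-positive patients")
    if table.n_neg < 1:
        raise ValidationError("specificity undefined: no reference-negative patients")
    sensitivity = table.tp / table.n_pos
    specificity = table.tn / table.n_neg
    if table.tn + table.fn < 1:
        raise ValidationError("NPV undefined: no scheme-negative patients")
    npv = table.tn / (table.tn + table.fn)
    accuracy = (table.tp + table.tn) / table.n
    auc = (sensitivity + specificity) / 2.0
    return SchemeMetrics(
        k=k, table=table, sensitivity=sensitivity, npv=npv,
        accuracy=accuracy, specificity=specificity, auc=auc,
    )


def auc_ci(table: ContingencyTable, method: str = "hanley_mcneil", level: float = 0.95) -> tuple:
    """Two-sided confidence interval for the single-threshold AUC.

    ``hanley_mcneil`` uses SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2)
    + (n_neg-1)(Q2-A^2)] / (n_pos * n_neg) with Q1 = A/(2-A) and
    Q2 = 2A^2/(1+A).  ``wald_halfsum`` propagates binomial variances of
    sensitivity and specificity through the half-sum.  Both intervals
    are clipped to [0, 1].
    """
    if method not in CI_METHODS:
        raise ValidationError(f"unknown CI method {method!r}; valid: {CI_METHODS}")
    if not 0 < level < 1:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    if table.n_pos < 1 or table.n_neg < 1:
        raise ValidationError("AUC CI requires at least one positive and one negative")
    m = metrics_from_table(table)
    a = m.auc
    if method == "hanley_mcneil":
        q1 = a / (2.0 - a)
        q2 = 2.0 * a * a / (1.0 + a)
        se2 = (a * (1.0 - a) + (table.n_pos - 1) * (q1 - a * a) + (table.n_neg - 1) * (q2 - a * a))
        se2 /= table.n_pos * table.n_neg
    else:
        se2 = (m.sensitivity * (1.0 - m.sensitivity) / table.n_pos
               + m.specificity * (1.0 - m.specificity) / table.n_neg) / 4.0
    se = float(np.sqrt(max(se2, 0.0)))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return (max(0.0, a - z * se), min(1.0, a + z * se))


def mcnemar_exact(discordant_b: int, discordant_c: int) -> float:
    """Exact two-sided McNemar p-value for paired binary outcomes.

    Uses the two-sided doubling rule on the binomial distribution of
    the smaller discordant count under p0 = 0.5:
    ``p = min(1, 2 * P(X <= min(b, c)))`` with ``X ~ Bin(b + c, 0.5)``.
    For more than 25 discordant pairs the continuity-corrected
    chi-square approximation is used instead.
    """
    b, c = int(discordant_b), int(discordant_c)
    if b < 0 or c < 0:
        raise ValidationError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    if n > 25:
        chi2 = max(abs(b - c) - 1.0, 0.0) ** 2 / n
        return float(stats.chi2.sf(chi2, df=1))
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))


def evaluate_schemes(patients, ks=None, grade_threshold: int = 1,
                     ci_method: str = "hanley_mcneil", level: float = 0.95) -> list:
    """Full metric series (one :class:`SchemeMetrics` per k).

    ``ks`` defaults to 1..n over the ranking length of the first
    patient; gaps are allowed (missing k values are simply not
    evaluated).  The McNemar test compares each reduced scheme with the
    reference, i.e. discordant counts (fp, fn).
    """
    patients = list(patients)
    if not patients:
        raise ValidationError("patient list is empty")
    n_ranked = len(list(patients[0][1]))
    if ks is None:
        ks = range(1, n_ranked + 1)
    series = []
    for k in ks:
        table = tabulate_scheme(patients, k, grade_threshold=grade_threshold)
        m = metrics_from_table(table, k=k)
        m = replace(
            m,
            auc_ci=auc_ci(table, method=ci_method, level=level),
            mcnemar_p=mcnemar_exact(table.fp, table.fn),
        )
        series.append(m)
    return series
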