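"""Disease Risk Score (DRS) model and quintile risk stratification.

The DRS is the predicted probability of a positive 12-core systematic
biopsy under a logistic model with eight covariates: age (years),
BMI (kg/m^2), total PSA (ng/ml), the three prostate diameters measured
on T2WI (transverse, anteroposterior, cephalocaudal; cm), the lesion's
longest diameter (cm), and the PI-RADS v2 score entered as its raw
numeric value (3, 4 or 5).  Patients are stratified into five
equal-frequency layers by the empirical 20/40/60/80 percentiles of
their scores; each layer later receives its own reduced core count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields

import numpy as np
from scipy.special import expit

from .errors import FitError, StratificationError, ValidationError

__all__ = [
    "CovariateVector",
    "DRSCoefficients",
    "PUBLISHED",
    "RiskStratification",
    "compute_drs",
    "fit_coefficients",
    "make_strata",
    "assign_layer",
    "assign_layers",
]

#: Covariate order X1..X8 expected by the coefficient vector.
COVARIATE_ORDER = (
    "age",
    "bmi",
    "tpsa",
    "transverse_diameter",
    "anteroposterior_diameter",
    "cephalocaudal_diameter",
    "lesion_longest_diameter",
    "pirads",
)

_VALID_PIRADS = (3, 4, 5)


@dataclass(frozen=True)
class CovariateVector:
    """One patient's risk-model covariates.

    All continuous fields must be strictly positive and finite;
    ``pirads`` must be 3, 4 or 5 (lesions below PI-RADS 3 fall outside
    the model's inclusion criteria).
    """

    age: float
    bmi: float
    tpsa: float
    transverse_diameter: float
    anteroposterior_diameter: float
    cephalocaudal_diameter: float
    lesion_longest_diameter: float
    pirads: int

    def validate(self) -> "CovariateVector":
        for name in COVARIATE_ORDER[:-1]:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValidationError(f"covariate '{name}' must be finite, got {value!r}")
            if value <= 0:
                raise ValidationError(f"covariate '{name}' must be strictly positive, got {value!r}")
        if self.pirads not in _VALID_PIRADS:
            raise ValidationError(f"covariate 'pirads' must be one of {_VALID_PIRADS}, got {self.pirads!r}")
        return self

    def as_array(self) -> np.ndarray:
        """Covariates as a length-8 float array in X1..X8 order."""
        return np.array([float(getattr(self, name)) for name in COVARIATE_ORDER])


@dataclass(frozen=True)
class DRSCoefficients:
    """Intercept and eight slopes of the logistic risk model."""

    intercept: float
    beta: tuple

    def __post_init__(self):
        beta = tuple(float(b) for b in self.beta)
        object.__setattr__(self, "beta", beta)
        if len(beta) != 8:
            raise ValidationError(f"expected 8 slopes, got {len(beta)}")
        if not np.isfinite(self.intercept) or not all(np.isfinite(beta)):
            raise ValidationError("coefficients must be finite")

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "beta": list(self.beta)}

    @classmethod
    def from_dict(cls, payload: dict) -> "DRSCoefficients":
        return cls(intercept=float(payload["intercept"]), beta=tuple(payload["beta"]))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "DRSCoefficients":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


#: The published coefficient set of the risk model.
PUBLISHED = DRSCoefficients(
    intercept=-5.57,
    beta=(0.062, 0.055, 0.015, -0.531, -0.171, -0.374, -0.301, 1.680),
)


def compute_drs(cov: CovariateVector, coef: DRSCoefficients = PUBLISHED, *, validate: bool = True) -> float:
    """Evaluate the logistic risk score 1 / (1 + exp(-eta)).

    ``eta`` is the linear predictor ``intercept + sum(beta_i * X_i)``.
    The result is a probability strictly inside (0, 1).  Set
    ``validate=False`` to bypass the covariate range checks (useful for
    purely numerical evaluation of the formula).
    """
    if validate:
        cov.validate()
    eta = coef.intercept + float(np.dot(coef.beta, cov.as_array()))
    return float(expit(eta))


def fit_coefficients(cohort) -> DRSCoefficients:
    """Refit the logistic model by unpenalized maximum likelihood.

    Parameters
    ----------
    cohort
        Sequence of ``(CovariateVector, cancer_status)`` pairs, where
        ``cancer_status`` is 0/1 (reference-standard biopsy outcome).

    Raises
    ------
    FitError
        For cohorts below 50 patients, single-class outcomes, complete
        separation, or a singular design matrix.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    pairs = list(cohort)
    if len(pairs) < 50:
        raise FitError(f"need at least 50 patients to refit, got {len(pairs)}")
    X = np.vstack([cov.validate().as_array() for cov, _ in pairs])
    y = np.array([int(status) for _, status in pairs])
    if y.min() == y.max():
        raise FitError("outcome has a single class; cannot fit a logistic model")
    try:
        result = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(result.params)
    if not result.mle_retvals.get("converged", False) or not np.all(np.isfinite(params)):
        raise FitError("logistic fit did not converge (possible separation or singular design)")
    # Huge coefficients with exploding standard errors indicate quasi-separation.
    if np.any(np.abs(params) > 50) or not np.all(np.isfinite(np.asarray(result.bse))):
        raise FitError("logistic fit is degenerate (quasi-complete separation)")
    return DRSCoefficients(intercept=float(params[0]), beta=tuple(params[1:]))


@dataclass(frozen=True)
class RiskStratification:
    """Quintile cutpoints (P20, P40, P60, P80) of a training score set."""

    cutpoints: tuple
    n_layers: int = 5

    def __post_init__(self):
        cp = tuple(float(c) for c in self.cutpoints)
        object.__setattr__(self, "cutpoints", cp)
        if len(cp) != 4:
            raise ValidationError(f"expected 4 cutpoints, got {len(cp)}")
        if any(not (0.0 < c < 1.0) for c in cp):
            raise ValidationError("cutpoints must lie strictly within (0, 1)")
        if any(b < a for a, b in zip(cp, cp[1:])):
            raise ValidationError("cutpoints must be non-decreasing")
        if self.n_layers != 5:
            raise ValidationError("stratification is defined for exactly 5 layers")

    def to_dict(self) -> dict:
        return {"cutpoints": list(self.cutpoints), "n_layers": self.n_layers}

    @classmethod
    def from_dict(cls, payload: dict) -> "RiskStratification":
        return cls(cutpoints=tuple(payload["cutpoints"]))


def make_strata(scores) -> RiskStratification:
    """Build quintile strata from training scores.

    Cutpoints are the empirical 20/40/60/80 percentiles computed with
    the linear-interpolation quantile rule.  Requires at least five
    distinct scores; heavily tied inputs (e.g. all scores identical)
    are rejected because no equal-frequency split exists.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 5:
        raise StratificationError(f"need at least 5 scores, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise StratificationError("scores must be finite")
    if np.unique(arr).size < 5:
        raise StratificationError("need at least 5 distinct scores to form quintile layers")
    cutpoints = np.percentile(arr, [20, 40, 60, 80], method="linear")
    return RiskStratification(cutpoints=tuple(cutpoints))


def assign_layer(score: float, strata: RiskStratification) -> int:
    """Map a score to its risk layer (1 = lowest risk ... 5 = highest).

    Boundary convention: a score exactly equal to a cutpoint belongs to
    the upper layer (intervals are closed on the left at each cutpoint).
    Ties therefore all land in the same layer.
    """
    if not np.isfinite(score):
        raise ValidationError(f"score must be finite, got {score!r}")
    return 1 + int(sum(score >= c for c in strata.cutpoints))


def assign_layers(scores, strata: RiskStratification) -> np.ndarray:
    """Vectorized :func:`assign_layer`."""
    arr = np.asarray(list(scores), dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("scores must be finite")
    return 1 + (arr[:, None] >= np.asarray(strata.cutpoints)[None, :]).sum(axis=1)
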