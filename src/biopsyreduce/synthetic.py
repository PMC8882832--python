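"""Seed-reproducible synthetic cohorts for the biopsy-reduction pipeline.

The generator emulates the covariate structure of the modeling cohort:
age is near-normal; BMI, total PSA, the three prostate diameters and
the lesion diameter are log-normal, parameterized by their published
median and quartiles; PI-RADS is multinomial.  Cancer status is
Bernoulli with probability equal to the Disease Risk Score of the
generating coefficients, so refitting the logistic model on a large
generated cohort is a parameter-recovery experiment.

For biopsy-positive patients, per-core positivity decays with the
squared distance between the core and the true lesion center:
``p_hit = p_peak(PI-RADS) * exp(-d^2 / (2 sigma_eff^2)) + background``,
and the core pattern is rejection-sampled until at least one core is
positive, because the modeled cohorts are defined by biopsy outcome
rather than latent disease.  Two mechanisms tie detection difficulty
to risk, mirroring clinical experience: higher PI-RADS lesions are
more conspicuous (larger peak hit probability) and better localized
(the true center sits closer to the sector centroid the clinician
reads off mpMRI), while larger glands dilute the per-core hit
probability (``sigma_eff = sigma * (gland_ref / gland_size)``, with
gland size the geometric mean of the three diameters).  High-risk
layers are therefore detectable with fewer cores, reproducing the
decreasing per-layer core-count pattern of the modeled study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .drs import PUBLISHED, CovariateVector, DRSCoefficients, RiskStratification, compute_drs
from .errors import GenerationError, ValidationError
from .evaluation import CoreOutcomes
from .geometry import CoreLayout, LesionLocation, get_layout, rank_cores, sector_centroid
from .io import PatientRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "summarize_cohort",
    "make_table2_fixture",
    "make_table3_fixture",
]

# Median/quartile calibration of the log-normal covariates.  The
# published TPSA lower quartile is taken as 7.36 ng/ml (the printed
# "87.36" is a typo; the positive-group Q1 is 7.26).
_LOGNORMAL_DEFAULTS = {
    "bmi": (24.22, 22.49, 26.14),
    "tpsa": (10.8, 7.36, 17.45),
    "transverse_diameter": (4.9, 4.5, 5.3),
    "anteroposterior_diameter": (3.4, 2.9, 4.0),
    "cephalocaudal_diameter": (4.0, 3.5, 4.7),
    "lesion_longest_diameter": (1.5, 1.0, 2.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters (defaults calibrated to the modeling cohort)."""

    n: int = 609
    seed: int = 0
    age_mean: float = 68.32
    age_sd: float = 8.01
    lognormal: dict = field(default_factory=lambda: dict(_LOGNORMAL_DEFAULTS))
    pirads_probs: tuple = (197 / 609, 241 / 609, 171 / 609)
    side_probs: tuple = (0.5, 0.5)            # left, right
    level_probs: tuple = (0.3, 0.4, 0.3)      # base, mid, apex
    zone_probs: tuple = (0.7, 0.3)            # peripheral, transition
    sigma: float = 0.33                       # spatial decay, normalized units
    peak_hit: dict = field(default_factory=lambda: {3: 0.40, 4: 0.72, 5: 0.95})
    background_hit: float = 0.015             # multifocal background per core
    # MRI localization error (sd of true center vs sector centroid) by PI-RADS
    lesion_jitter_sd: dict = field(default_factory=lambda: {3: 0.55, 4: 0.28, 5: 0.08})
    gland_ref: float = 4.1                    # reference gland diameter, cm
    cs_fraction: float = 0.85                 # csPCa fraction among positives
    max_rejections: int = 1000
    coefficients: DRSCoefficients = PUBLISHED

    def validate(self) -> "SyntheticConfig":
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if self.sigma <= 0 or self.gland_ref <= 0:
            raise ValidationError("sigma and gland_ref must be > 0")
        for grade, sd in self.lesion_jitter_sd.items():
            if sd < 0:
                raise ValidationError(f"lesion_jitter_sd[{grade}] must be >= 0")
        for name, probs in (("pirads_probs", self.pirads_probs), ("side_probs", self.side_probs),
                            ("level_probs", self.level_probs), ("zone_probs", self.zone_probs)):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
                raise ValidationError(f"{name} must be non-negative and sum to 1")
        for name in ("background_hit", "cs_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be within [0, 1]")
        for grade, p in self.peak_hit.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"peak_hit[{grade}] must be within [0, 1]")
        return self

    def to_dict(self) -> dict:
        payload = {
            "n": self.n, "seed": self.seed, "age_mean": self.age_mean, "age_sd": self.age_sd,
            "lognormal": {k: list(v) for k, v in self.lognormal.items()},
            "pirads_probs": list(self.pirads_probs), "side_probs": list(self.side_probs),
            "level_probs": list(self.level_probs), "zone_probs": list(self.zone_probs),
            "sigma": self.sigma, "peak_hit": {str(k): v for k, v in self.peak_hit.items()},
            "background_hit": self.background_hit,
            "lesion_jitter_sd": {str(k): v for k, v in self.lesion_jitter_sd.items()},
            "gland_ref": self.gland_ref,
            "cs_fraction": self.cs_fraction, "max_rejections": self.max_rejections,
            "coefficients": self.coefficients.to_dict(),
        }
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        payload = dict(payload)
        if "lognormal" in payload:
            payload["lognormal"] = {k: tuple(v) for k, v in payload["lognormal"].items()}
        if "peak_hit" in payload:
            payload["peak_hit"] = {int(k): float(v) for k, v in payload["peak_hit"].items()}
        if "lesion_jitter_sd" in payload:
            payload["lesion_jitter_sd"] = {int(k): float(v) for k, v in payload["lesion_jitter_sd"].items()}
        if "coefficients" in payload:
            payload["coefficients"] = DRSCoefficients.from_dict(payload["coefficients"])
        for name in ("pirads_probs", "side_probs", "level_probs", "zone_probs"):
            if name in payload:
                payload[name] = tuple(payload[name])
        return cls(**payload)

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated patients plus the configuration that produced them."""

    patients: tuple
    config: SyntheticConfig
    layout_name: str

    def __len__(self):
        return len(self.patients)


def _lognormal_params(median: float, q1: float, q3: float):
    sigma = np.log(q3 / q1) / (2.0 * stats.norm.ppf(0.75))
    return np.log(median), sigma


def generate_cohort(config: SyntheticConfig, layout: CoreLayout = None) -> SyntheticCohort:
    """Draw a reproducible synthetic cohort under ``config``.

    Cancer-positive patients are conditioned on 12-core detectability by
    redrawing their core pattern until at least one core is positive
    (bounded by ``config.max_rejections``).
    """
    config.validate()
    if layout is None:
        layout = get_layout("changhai_12")
    rng = np.random.default_rng(config.seed)
    n = config.n

    age = np.maximum(rng.normal(config.age_mean, config.age_sd, n), 30.0)
    cont = {}
    for name, (med, q1, q3) in config.lognormal.items():
        mu, s = _lognormal_params(med, q1, q3)
        cont[name] = rng.lognormal(mu, s, n)
    pirads = rng.choice([3, 4, 5], size=n, p=np.asarray(config.pirads_probs))
    sides = rng.choice(["left", "right"], size=n, p=np.asarray(config.side_probs))
    levels = rng.choice(["base", "mid", "apex"], size=n, p=np.asarray(config.level_probs))
    zones = rng.choice(["peripheral", "transition"], size=n, p=np.asarray(config.zone_probs))

    X = np.column_stack([
        age, cont["bmi"], cont["tpsa"], cont["transverse_diameter"],
        cont["anteroposterior_diameter"], cont["cephalocaudal_diameter"],
        cont["lesion_longest_diameter"], pirads,
    ])
    eta = config.coefficients.intercept + X @ np.asarray(config.coefficients.beta)
    p_cancer = 1.0 / (1.0 + np.exp(-eta))
    cancer = rng.random(n) < p_cancer

    centroids = np.vstack([
        sector_centroid(LesionLocation(side=s, level=l, zone=z))
        for s, l, z in zip(sides, levels, zones)
    ])
    jitter_sd = np.vectorize(config.lesion_jitter_sd.__getitem__)(pirads).astype(float)
    true_centers = np.clip(centroids + rng.normal(0.0, 1.0, (n, 3)) * jitter_sd[:, None], -1.0, 1.0)

    positions = layout.positions()                     # (n_cores, 3)
    d2 = ((true_centers[:, None, :] - positions[None, :, :]) ** 2).sum(axis=2)
    peak = np.vectorize(config.peak_hit.__getitem__)(pirads).astype(float)
    gland = (cont["transverse_diameter"] * cont["anteroposterior_diameter"]
             * cont["cephalocaudal_diameter"]) ** (1.0 / 3.0)
    sigma_eff = config.sigma * (config.gland_ref / gland)
    p_hit = np.clip(peak[:, None] * np.exp(-d2 / (2.0 * sigma_eff[:, None] ** 2)) + config.background_hit,
                    0.0, 0.98)

    hits = np.zeros((n, layout.n), dtype=bool)
    pos_idx = np.flatnonzero(cancer)
    pending = pos_idx.copy()
    for _ in range(config.max_rejections):
        if pending.size == 0:
            break
        draw = rng.random((pending.size, layout.n)) < p_hit[pending]
        hits[pending] = draw
        pending = pending[~draw.any(axis=1)]
    if pending.size:
        raise GenerationError(
            f"{pending.size} positive patients produced no positive core after "
            f"{config.max_rejections} redraws; increase peak_hit or background_hit"
        )

    cs_flags = rng.random(n) < config.cs_fraction
    patients = []
    for i in range(n):
        cov = CovariateVector(
            age=float(age[i]), bmi=float(cont["bmi"][i]), tpsa=float(cont["tpsa"][i]),
            transverse_diameter=float(cont["transverse_diameter"][i]),
            anteroposterior_diameter=float(cont["anteroposterior_diameter"][i]),
            cephalocaudal_diameter=float(cont["cephalocaudal_diameter"][i]),
            lesion_longest_diameter=float(cont["lesion_longest_diameter"][i]),
            pirads=int(pirads[i]),
        )
        lesion = LesionLocation(side=str(sides[i]), level=str(levels[i]), zone=str(zones[i]))
        flags = hits[i]
        isup = np.zeros(layout.n, dtype=int)
        if flags.any():
            hit_ids = np.flatnonzero(flags)
            if cs_flags[i]:
                isup[hit_ids] = rng.choice([1, 2, 3], size=hit_ids.size, p=[0.3, 0.5, 0.2])
                # the core closest to the lesion carries the dominant (csPCa) grade
                dominant = hit_ids[np.argmin(d2[i, hit_ids])]
                isup[dominant] = max(isup[dominant], int(rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1])))
            else:
                isup[hit_ids] = 1
        patients.append(PatientRecord(
            patient_id=f"S{i + 1:05d}", covariates=cov, lesion=lesion,
            outcomes=CoreOutcomes(positive=tuple(bool(f) for f in flags), isup=tuple(int(g) for g in isup)),
        ))
    return SyntheticCohort(patients=tuple(patients), config=config, layout_name=layout.name)


def summarize_cohort(cohort: SyntheticCohort) -> pd.DataFrame:
    """Descriptive table split by reference status.

    Tidy output: one row per (variable, group, statistic) with numeric
    values; groups are ``total``, ``positive``, ``negative``.
    """
    patients = list(cohort.patients)
    if not patients:
        raise ValidationError("cohort is empty")
    frame = pd.DataFrame({
        "age": [p.covariates.age for p in patients],
        "bmi": [p.covariates.bmi for p in patients],
        "tpsa": [p.covariates.tpsa for p in patients],
        "transverse_diameter": [p.covariates.transverse_diameter for p in patients],
        "anteroposterior_diameter": [p.covariates.anteroposterior_diameter for p in patients],
        "cephalocaudal_diameter": [p.covariates.cephalocaudal_diameter for p in patients],
        "lesion_longest_diameter": [p.covariates.lesion_longest_diameter for p in patients],
        "pirads": [p.covariates.pirads for p in patients],
        "positive": [p.reference_positive for p in patients],
    })
    groups = {"total": frame, "positive": frame[frame["positive"]], "negative": frame[~frame["positive"]]}
    rows = []
    for group, sub in groups.items():
        rows.append({"variable": "n", "group": group, "statistic": "count", "value": float(len(sub))})
        if len(sub) == 0:
            continue
        rows.append({"variable": "age", "group": group, "statistic": "mean", "value": sub["age"].mean()})
        rows.append({"variable": "age", "group": group, "statistic": "sd", "value": sub["age"].std(ddof=1) if len(sub) > 1 else 0.0})
        for var in ("bmi", "tpsa", "transverse_diameter", "anteroposterior_diameter",
                    "cephalocaudal_diameter", "lesion_longest_diameter"):
            q1, med, q3 = sub[var].quantile([0.25, 0.5, 0.75])
            rows += [
                {"variable": var, "group": group, "statistic": "median", "value": med},
                {"variable": var, "group": group, "statistic": "q1", "value": q1},
                {"variable": var, "group": group, "statistic": "q3", "value": q3},
            ]
        for score in (3, 4, 5):
            count = int((sub["pirads"] == score).sum())
            rows += [
                {"variable": f"pirads_{score}", "group": group, "statistic": "count", "value": float(count)},
                {"variable": f"pirads_{score}", "group": group, "statistic": "percent",
                 "value": 100.0 * count / len(sub)},
            ]
    return pd.DataFrame(rows, columns=["variable", "group", "statistic", "value"])


# --- deterministic count-backed fixtures -------------------------------------

# Cumulative layer-1 detections by k (reference-positive patients whose
# first positive ranked core sits at each position).
_LAYER1_FIRST_HIT = [1] * 17 + [2] * 8 + [4] * 2 + [5] * 1 + [6] * 2 + [7] * 1 + [9] * 3 + [10] * 1
_LAYER1_N_NEG = 87


def make_table2_fixture():
    """Deterministic 122-patient layer-1 fixture (synthetic stand-in).

    35 reference-positive and 87 reference-negative patients whose
    per-k detection counts walk through 17, 25, 25, 27, 28, 30, 31, 31,
    34, 35, 35 for k = 1..11.  Each positive patient carries a single
    positive core at their first-detection rank position; rankings are
    the identity permutation.  Returns ``(CoreOutcomes, ranking)``
    pairs ready for :func:`~biopsyreduce.evaluation.tabulate_scheme`.
    """
    ranking = list(range(1, 13))
    patients = []
    for pos in _LAYER1_FIRST_HIT:
        flags = [False] * 12
        flags[pos - 1] = True
        isup = [0] * 12
        isup[pos - 1] = 2
        patients.append((CoreOutcomes(positive=tuple(flags), isup=tuple(isup)), list(ranking)))
    benign = CoreOutcomes(positive=(False,) * 12, isup=(0,) * 12)
    for _ in range(_LAYER1_N_NEG):
        patients.append((benign, list(ranking)))
    return patients


# Per-layer validation counts: layer -> (k, n, detected, missed csPCa).
_VALIDATION_COUNTS = {2: (6, 25, 22, 1), 3: (5, 28, 27, 0), 4: (4, 78, 74, 0), 5: (4, 148, 140, 4)}
_VALIDATION_CUTPOINTS = (0.2, 0.4, 0.6, 0.8)
_VALIDATION_DRS_TARGETS = {2: 0.3, 3: 0.5, 4: 0.7, 5: 0.9}


def make_table3_fixture():
    """Deterministic external-validation fixture (synthetic stand-in).

    Builds an all-reference-positive cohort of 279 patients spread over
    layers 2..5 (layer 1 empty) together with a matching
    :class:`~biopsyreduce.selection.LayerPlan` (cutpoints 0.2/0.4/0.6/
    0.8, core counts 9/6/5/4/4).  Covariates sit at the modeling
    cohort's central values except age, which is solved so each
    patient's DRS lands mid-layer.  Detected patients carry their
    positive core at the nearest ranked position; missed patients at
    the farthest, with ISUP grades matching the published
    csPCa-miss pattern.  Returns ``(cohort, plan)``.
    """
    from .selection import LayerPlan  # local import to avoid a cycle

    layout = get_layout("changhai_12")
    base = dict(
        bmi=24.22, tpsa=10.8, transverse_diameter=4.9, anteroposterior_diameter=3.4,
        cephalocaudal_diameter=4.0, lesion_longest_diameter=1.5, pirads=4,
    )
    # linear predictor without the age term, at the central covariates
    eta_rest = PUBLISHED.intercept + float(np.dot(
        PUBLISHED.beta[1:],
        [base["bmi"], base["tpsa"], base["transverse_diameter"], base["anteroposterior_diameter"],
         base["cephalocaudal_diameter"], base["lesion_longest_diameter"], base["pirads"]],
    ))
    lesion = LesionLocation(side="right", level="base", zone="peripheral")
    ranking = [cid for cid in rank_cores(lesion, layout)]
    near, far = ranking[0], ranking[-1]

    cohort = []
    pid = 0
    for layer, (k, n, detected, missed_cs) in _VALIDATION_COUNTS.items():
        target = _VALIDATION_DRS_TARGETS[layer]
        age = (np.log(target / (1.0 - target)) - eta_rest) / PUBLISHED.beta[0]
        cov = CovariateVector(age=float(age), **base).validate()
        n_missed = n - detected
        for j in range(n):
            pid += 1
            flags = [False] * 12
            isup = [0] * 12
            if j < detected:
                flags[near - 1] = True
                isup[near - 1] = 2 if j % 2 == 0 else 1
            else:
                miss_index = j - detected
                flags[far - 1] = True
                isup[far - 1] = 2 if miss_index < missed_cs else 1
            cohort.append(PatientRecord(
                patient_id=f"V{pid:04d}", covariates=cov, lesion=lesion,
                outcomes=CoreOutcomes(positive=tuple(flags), isup=tuple(isup)),
            ))
    plan = LayerPlan(
        strata=RiskStratification(cutpoints=_VALIDATION_CUTPOINTS),
        core_counts=(9, 6, 5, 4, 4), layout_name=layout.name, coefficients=PUBLISHED,
    )
    return cohort, plan
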