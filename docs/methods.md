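# Methods

## The problem

Twelve-core transrectal systematic prostate biopsy (12-SBx) is the reference procedure for
tissue diagnosis in men with an MRI-visible lesion (PI-RADS ≥ 3), but every core adds risk of
bleeding, infection and discomfort. This package implements an individualized core-reduction
pipeline: patients are stratified by a pre-biopsy risk score, and each risk stratum is assigned
the smallest number of cores — taken closest to the MRI lesion — that remains non-inferior to
the full 12-core template.

## Disease Risk Score

The risk of a positive 12-core biopsy is modeled as a logistic regression on eight covariates,

    DRS = 1 / (1 + exp(−η)),
    η = −5.57 + 0.062·age + 0.055·BMI + 0.015·TPSA − 0.531·DT − 0.171·DAP − 0.374·DCC
        − 0.301·DL + 1.680·PIRADS

with age in years, BMI in kg/m², total PSA in ng/ml, the three prostate diameters (transverse
DT, anteroposterior DAP, cephalocaudal DCC) and the lesion's longest diameter DL in cm, and the
PI-RADS v2 score entered as its raw number (3/4/5), not as indicator contrasts. These published
coefficients ship as the constant `PUBLISHED` and are never silently replaced;
`fit_coefficients` refits the same model by unpenalized maximum likelihood (statsmodels) and
raises on separation, singular designs, single-class outcomes or n < 50.

Patients are split into five equal-frequency layers at the empirical 20/40/60/80 percentiles of
the training scores (linear-interpolation quantile rule). A score exactly equal to a cutpoint
belongs to the upper layer; ties at a cutpoint therefore all land in one layer, accepting
imbalance under heavy ties. With distinct scores the layer sizes differ by at most one.

## Core templates and lesion geometry

The prostate is a unit box: x left→right, y posterior→anterior, z base→apex, each in [−1, 1].
The paper's diagrams give no coordinates, so the package ships a canonical, versioned coordinate
table: the 12-core template is {left,right} × {base,mid,apex} × {medial,lateral} with
medial |x| = 0.25, lateral |x| = 0.75, all cores posterior at y = −0.5, and base/mid/apex at
z = −0.7/0/+0.7. The 13-core template adds one midline core at (0, −0.5, 0); because it maps to
no 12-core position it is excluded from the 12-core reference and from reduced-scheme rankings
(a warning is emitted when such a layout is processed).

A lesion is located by coarse sector labels — side × level × zone (peripheral/transition), the
granularity a clinician reads off mpMRI — or by explicit coordinates. Sector centroids:
peripheral (±0.5, −0.5, z-level), transition (±0.3, 0.0, z-level); the transition centroid sits
on the mid-gland plane so that anterior lesions remain reachable by the posterior template, at a
realistic disadvantage. Cores are ranked by Euclidean distance from the lesion point
(isotropic, i.e. no rescaling by the measured gland diameters — a documented simplification);
distance ties break by level (base < mid < apex), then side (right < left), then core id. The
k-core scheme is the length-k prefix, so schemes are nested by construction.

## Scheme evaluation

For each layer and each k, patients are cross-tabulated as reduced-scheme result × 12-core
reference result. The reference is always detection over all 12 standard cores at ISUP ≥ 1,
even when reduced schemes are scored at a csPCa threshold (ISUP ≥ 2). Nesting forces fp = 0 and
specificity = 1, so the single-threshold AUC is exactly (1 + sensitivity)/2; sensitivity, NPV
and accuracy follow the usual 2×2 definitions. Proportions are kept unrounded internally;
percent columns are formatted to two decimals (round half up) only at the I/O boundary.

The AUC confidence interval defaults to Hanley–McNeil:

    SE² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)] / (n₊·n₋),
    Q₁ = A/(2−A),  Q₂ = 2A²/(1+A)

clipped to [0, 1]; a Wald half-sum variant is available for sensitivity analysis. On the
shipped layer-1 count fixture the Hanley–McNeil endpoints sit within 0.008 of every printed
interval; exact agreement is not expected because the original software's CI variant is unknown.

Paired detection rates are compared with McNemar's test on the discordant counts (fp, fn):
exact two-sided doubling rule p = min(1, 2·P(X ≤ min(b,c))), X ~ Bin(b+c, ½), for b+c ≤ 25, and
the continuity-corrected chi-square (correction clamped at zero so b = c gives p = 1) above.
Published p-values mix one- and two-sided conventions; this package standardizes on two-sided.

## Core-number selection and validation

Within each layer the selected core count is the smallest evaluated k whose two-sided 95% CI
lower bound for the AUC is ≥ 0.95, falling back to 12 when none qualifies; missing k values
(unavailable rows) are skipped, never interpolated. Layers without reference-positive patients
are skipped with a warning. The plan records its strata, coefficients, layout, CI method and
grade threshold so validation and recommendation reproduce the exact selection basis.

External validation applies a trained plan to an all-biopsy-positive cohort, stratifying with
the *training* cutpoints. Per layer it reports n, the number detected at the selected k, and
two accuracies: at ISUP ≥ 1, detected/n; at ISUP ≥ 2, a missed patient counts against the
scheme only if the missed cancer is clinically significant (patient-level max ISUP ≥ 2). The
detected/total reading at a raised threshold is arithmetically incompatible with the validation
counts this pipeline is built to reproduce, and the chosen definition makes
accuracy(ISUP≥2) ≥ accuracy(ISUP≥1) hold by construction. Patients without per-core grades are
conservatively treated as significant when missed. Empty layers are reported with n = 0, not
dropped.

The recommender composes scoring, layer assignment and ranking: it refuses PI-RADS < 3
(inclusion criterion), and returns the DRS, layer, the layer's core count k, and the k nearest
template cores — always the k-prefix of the ranking.

## Synthetic cohort generator

The generator emulates the modeling cohort so every stage is testable without patient data.

Covariates (independent by design): age ~ Normal(68.32, 8.01²) truncated at 30; BMI, TPSA,
DT, DAP, DCC and lesion diameter log-normal, parameterized by median and quartiles
(BMI 24.22 [22.49–26.14]; TPSA 10.8 [7.36–17.45] ng/ml — the lower quartile corrects an obvious
typo in the source table; DT 4.9 [4.5–5.3]; DAP 3.4 [2.9–4.0]; DCC 4.0 [3.5–4.7];
lesion 1.5 [1.0–2.0] cm); PI-RADS 3/4/5 multinomial with probabilities 0.3235/0.3957/0.2797.
Cancer status is Bernoulli with probability DRS(covariates) under the generating coefficients
(default `PUBLISHED`), which yields ≈ 74–75% biopsy-positive patients, matching the 454/609
split, and makes large-n refits a parameter-recovery experiment. Omitting covariate
correlations (e.g. PSA with gland volume) is a known simplification: it leaves the marginal
distributions and the risk model exact but slightly understates the variance inflation a real
refit would see.

Lesion sectors are sampled (side ½/½; level 0.3/0.4/0.3; zone peripheral 0.7 / transition 0.3).
For biopsy-positive patients each core is hit independently with

    p_hit = p_peak(PIRADS) · exp(−d² / (2·σ_eff²)) + background,
    σ_eff = σ · (gland_ref / gland),  gland = (DT·DAP·DCC)^(1/3)

where d is the distance from the core to the *true* lesion center — the sector centroid plus a
localization error with per-PI-RADS standard deviation. Defaults: σ = 0.33 (normalized units),
gland_ref = 4.1 cm, background = 0.015 per core (multifocality), p_peak = 0.40/0.72/0.95 and
localization sd = 0.55/0.28/0.08 for PI-RADS 3/4/5, csPCa fraction 0.85 among positives (the
closest positive core carries the dominant ≥ 2 grade). The two PI-RADS-linked gradients encode
that conspicuous high-grade lesions are both easier to hit and better localized on mpMRI, and
the gland term that a fixed template samples a large gland more sparsely. Together they make
high-risk layers detectable with fewer cores, reproducing the qualitative decreasing per-layer
core-count pattern (≈ 10/10/8/7/5 at n = 4000) that motivates stratified reduction; the exact
published 9/6/5/4/4 depends on unpublished per-layer series and is not a calibration target.
Positive patients are conditioned on 12-core detectability by redrawing their core pattern
(cap 1000, then an error suggesting larger hit probabilities), because the emulated cohorts are
defined by biopsy outcome, not latent disease. The generator does not emulate mpMRI images,
reader variability (PI-RADS is sampled, not derived), multi-lesion disease, or
covariate correlations — so passing tests demonstrate internal consistency of the pipeline
under these assumptions, not clinical performance.

Two count-backed fixtures are derived from the published tables rather than sampled: a
122-patient layer-1 fixture (35 positive / 87 negative) whose per-k detection counts walk
through the printed true-positive column, with each positive patient's single positive core
back-solved to its first-detection rank (positions 1×17, 2×8, 4×2, 5×1, 6×2, 7×1, 9×3, 10×1 —
any placement reproducing the counts is equivalent); and a 279-patient validation fixture
(layers 2–5 of sizes 25/28/78/148, layer 1 empty) with synthetic strata cutpoints 0.2/0.4/0.6/
0.8, covariates solved through the age term to land mid-layer, and the published csPCa-miss
pattern (1/0/0/4 significant misses).

## Numerical and testing choices

Quantiles use numpy's linear interpolation; CIs clip to [0, 1]; percent formatting is decimal
round-half-up; reports are written with fixed float formats and sorted keys so identical inputs
give identical bytes. Problem sizes in the test suite are the package's own choices balancing
statistical sharpness against a fast default run: plan-level properties at n = 4000 (one seed)
and n = 1500 (determinism), invariant sweeps at n = 120 over 100 seeds, calibration checks at
n = 2000–5000, parameter recovery at n = 8000 with 4-standard-error tolerances (a stricter
fixed-tolerance recovery check at n = 20,000 is also included; at that n several slope standard
errors are ≈ 0.02–0.03, so fixed absolute tolerances near 0.02 sit at the edge of sampling
noise for any single seed). Hypothesis-based property tests are bounded and seeded for
reproducibility.

## Known limitations

- The shipped coordinate table is canonical, not patient-specific; distances are isotropic in
  normalized units.
- The selection rule inherits the instability of CI lower bounds in small layers; with few
  reference positives the selected k is conservative (larger).
- The csPCa accuracy definition presumes per-core ISUP grades; ungraded cohorts are scored
  conservatively.
- External validation of the published kind requires an all-positive cohort by design; the
  package enforces this precondition rather than silently re-weighting.
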