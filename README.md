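# biopsyreduce

Individualized core-number reduction for systematic prostate biopsy, for biostatisticians and
urology researchers studying how many template cores a given patient actually needs.

Men with an MRI-visible prostate lesion (PI-RADS ≥ 3) conventionally undergo a 12-core
systematic biopsy; every core adds morbidity. This package implements a stratified
core-reduction pipeline:

1. **Disease Risk Score (DRS).** A logistic model of the probability of a positive 12-core
   biopsy, `DRS = 1/(1 + e^(−η))` with
   `η = −5.57 + 0.062·age + 0.055·BMI + 0.015·TPSA − 0.531·DT − 0.171·DAP − 0.374·DCC −
   0.301·DL + 1.680·PIRADS` (diameters in cm, PSA in ng/ml, PI-RADS as its raw 3/4/5 value).
   Published coefficients ship as `PUBLISHED`; `fit_coefficients` refits by maximum likelihood.
2. **Quintile stratification.** Five equal-frequency risk layers at the empirical
   P20/P40/P60/P80 cutpoints of the training scores.
3. **Lesion-distance schemes.** Template cores ranked by distance from the MRI lesion; the
   k-core scheme is the k nearest cores, so schemes are nested and false positives against the
   12-core reference are structurally zero (AUC = (1 + sensitivity)/2).
4. **Non-inferiority selection.** Per layer, the smallest k whose Hanley–McNeil 95% CI lower
   bound for the AUC is ≥ 0.95 (exact McNemar tests accompany each comparison).
5. **External validation and recommendation.** A trained plan is applied to an external
   biopsy-positive cohort with the training cutpoints, and a recommender returns each
   patient's DRS, layer, core count and core map — the logic of the clinical web tool.

A seed-reproducible synthetic cohort generator (covariates, DRS-driven cancer status,
lesion-centered per-core positivity) makes every stage testable without patient data; see
`docs/methods.md` for the model and its assumptions.

## Worked example

Generate a cohort, build a plan, and ask for a recommendation:

```sh
biopsy-reduce simulate --n 2000 --seed 17 --out cohort.csv
biopsy-reduce select --cohort cohort.csv --out plan.json
biopsy-reduce recommend --age 68 --bmi 24.22 --tpsa 10.8 \
    --dia-transverse 4.9 --dia-ap 3.4 --dia-cc 4.0 --lesion-diameter 1.5 \
    --pirads 4 --side right --level base --zone peripheral --plan plan.json
```

prints

```
wrote 2000 patients to cohort.csv
selected core counts: [10, 10, 8, 7, 7]
{"cores": [1, 2, 5, 6, 3, 7, 4, 9], "drs": 0.8493, "layer": 3}
      left        right
   lat   med | med   lat
base [ 4] [ 3] | [ 1] [ 2]
mid    8  [ 7] | [ 5] [ 6]
apex  12   11  | [ 9]  10
```

The plan line is the per-layer core count selected by the CI rule on this synthetic training
cohort (lowest-risk layer first; higher-risk layers need fewer cores). The recommendation says
this patient's DRS is 0.8493, placing him in layer 3 of that plan, so 8 of the 12 template
cores suffice — the bracketed cores in the map, those nearest his right-base peripheral lesion.

The same flow is available as a library (`generate_cohort`, `build_plan`, `recommend`), and
`evaluate_schemes` / `external_validate` produce the per-k metric tables (sensitivity, NPV,
accuracy, AUC with 95% CI, McNemar p) and per-layer validation accuracies.

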