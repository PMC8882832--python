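"""Core-number selection, plan building, external validation, recommendation."""

import dataclasses
import io as std_io
import warnings

import numpy as np
import pytest

from biopsyreduce import (
    CovariateVector,
    EligibilityError,
    LayerPlan,
    LesionLocation,
    PUBLISHED,
    RiskStratification,
    SyntheticConfig,
    ValidationError,
    build_plan,
    evaluate_schemes,
    external_validate,
    generate_cohort,
    get_layout,
    make_table2_fixture,
    make_table3_fixture,
    rank_cores,
    recommend,
    select_core_number,
)
from biopsyreduce.io import report_frame


class TestSelectCoreNumber:
    def test_layer1_series_selects_nine(self, layer1_fixture):
        series = evaluate_schemes(layer1_fixture, ks=[1, 2, 4, 5, 6, 7, 9, 10, 11])
        assert select_core_number(series) == 9

    def test_gap_handling_skips_missing_k(self, layer1_fixture):
        # without k=9/10 available, the next qualifying k is selected
        series = evaluate_schemes(layer1_fixture, ks=[1, 2, 4, 5, 6, 7, 11])
        assert select_core_number(series) == 11

    def test_perfect_series_selects_one(self):
        from biopsyreduce import CoreOutcomes

        ranking = list(range(1, 13))
        hot = CoreOutcomes(positive=(True,) + (False,) * 11, isup=(2,) + (0,) * 11)
        cold = CoreOutcomes(positive=(False,) * 12, isup=(0,) * 12)
        patients = [(hot, ranking)] * 120 + [(cold, ranking)] * 120
        series = evaluate_schemes(patients)
        assert select_core_number(series) == 1

    def test_never_qualifying_series_falls_back_to_twelve(self, layer1_fixture):
        series = evaluate_schemes(layer1_fixture, ks=[1, 2, 4])
        assert select_core_number(series) == 12

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            select_core_number([])


@pytest.fixture(scope="module")
def training():
    cohort = generate_cohort(SyntheticConfig(n=4000, seed=0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plan, report = build_plan(list(cohort.patients))
    return cohort, plan, report


class TestBuildPlan:
    def test_selected_counts_non_increasing_across_layers(self, training):
        _, plan, _ = training
        ks = plan.core_counts
        assert all(k is not None for k in ks)
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_report_covers_all_layers_and_k(self, training):
        _, _, report = training
        assert set(report["layer"]) == {1, 2, 3, 4, 5}
        assert set(report["k"]) == set(range(1, 13))
        assert (report["fp"] == 0).all()

    def test_plan_deterministic_across_reruns(self):
        cfg = SyntheticConfig(n=1500, seed=42)
        outputs = []
        for _ in range(2):
            cohort = generate_cohort(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                plan, report = build_plan(list(cohort.patients))
            buf = std_io.StringIO()
            report.to_csv(buf, index=False)
            outputs.append((plan.to_dict(), buf.getvalue()))
        assert outputs[0] == outputs[1]

    def test_concentrated_signal_needs_at_most_two_cores(self):
        # tightly localized lesions: hits confined to the nearest template
        # cores (the peripheral sector centroid ties between two of them)
        cfg = SyntheticConfig(
            n=2500, seed=8, sigma=0.12, background_hit=0.0,
            peak_hit={3: 0.98, 4: 0.98, 5: 0.98},
            lesion_jitter_sd={3: 0.0, 4: 0.0, 5: 0.0},
            zone_probs=(1.0, 0.0),
        )
        cohort = generate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan, _ = build_plan(list(cohort.patients))
        assert all(k is not None and k <= 2 for k in plan.core_counts)

    def test_layer_without_positives_is_skipped_with_warning(self):
        cohort = generate_cohort(SyntheticConfig(n=400, seed=1))
        # strip positives whose score lands in the lowest quintile
        from biopsyreduce import CoreOutcomes, compute_drs, make_strata, assign_layer

        patients = list(cohort.patients)
        scores = [compute_drs(p.covariates) for p in patients]
        strata = make_strata(scores)
        benign = CoreOutcomes(positive=(False,) * 12, isup=(0,) * 12)
        stripped = [
            dataclasses.replace(p, outcomes=benign) if assign_layer(s, strata) == 1 else p
            for p, s in zip(patients, scores)
        ]
        with pytest.warns(UserWarning, match="selection skipped"):
            plan, _ = build_plan(stripped)
        assert plan.core_counts[0] is None


class TestExternalValidate:
    def test_reproduces_validation_count_table(self):
        cohort, plan = make_table3_fixture()
        report = external_validate(cohort, plan)
        frame = report.to_frame().set_index("layer")
        assert frame.loc[1, "n"] == 0
        acc1 = [round(100 * frame.loc[l, "accuracy_isup1"], 2) for l in (2, 3, 4, 5)]
        assert acc1 == [88.0, 96.43, 94.87, 94.59]
        acc2 = [round(100 * frame.loc[l, "accuracy_isup2"], 2) for l in (2, 3, 4, 5)]
        assert acc2 == [96.0, 100.0, 100.0, 97.3]

    def test_cspca_accuracy_never_below_overall_accuracy(self):
        cohort, plan = make_table3_fixture()
        frame = external_validate(cohort, plan).to_frame().dropna()
        assert (frame["accuracy_isup2"] >= frame["accuracy_isup1"]).all()

    def test_top_core_positive_everywhere_gives_full_accuracy(self):
        cohort, plan = make_table3_fixture()
        layout = get_layout(plan.layout_name)
        fixed = []
        for rec in cohort:
            ranking = rank_cores(rec.lesion, layout)
            flags = [False] * 12
            isup = [0] * 12
            flags[ranking[0] - 1] = True
            isup[ranking[0] - 1] = 2
            from biopsyreduce import CoreOutcomes

            fixed.append(dataclasses.replace(
                rec, outcomes=CoreOutcomes(positive=tuple(flags), isup=tuple(isup))))
        frame = external_validate(fixed, plan).to_frame().dropna()
        assert (frame["accuracy_isup1"] == 1.0).all()

    def test_reference_negative_patient_rejected(self):
        cohort, plan = make_table3_fixture()
        from biopsyreduce import CoreOutcomes

        bad = dataclasses.replace(
            cohort[0], outcomes=CoreOutcomes(positive=(False,) * 12, isup=(0,) * 12))
        with pytest.raises(ValidationError, match="reference-negative"):
            external_validate([bad] + cohort[1:], plan)


class TestRecommend:
    @pytest.fixture()
    def plan(self):
        return LayerPlan(
            strata=RiskStratification(cutpoints=(0.2, 0.4, 0.6, 0.8)),
            core_counts=(9, 6, 5, 4, 4), layout_name="changhai_12", coefficients=PUBLISHED,
        )

    def test_median_patient_right_base(self, plan, median_covariates, right_base_lesion):
        rec = recommend(median_covariates, right_base_lesion, plan)
        assert 1 <= rec.layer <= 5
        assert rec.k == plan.core_counts[rec.layer - 1]
        layout = get_layout("changhai_12")
        first = layout.core(rec.core_ids[0])
        assert first.side == "right" and first.level == "base"

    def test_core_set_is_ranking_prefix(self, plan, median_covariates, right_base_lesion):
        rec = recommend(median_covariates, right_base_lesion, plan)
        layout = get_layout("changhai_12")
        assert list(rec.core_ids) == rank_cores(right_base_lesion, layout)[: rec.k]

    def test_low_pirads_refused(self, plan, median_covariates, right_base_lesion):
        ineligible = dataclasses.replace(median_covariates, pirads=2)
        with pytest.raises(EligibilityError, match="PI-RADS"):
            recommend(ineligible, right_base_lesion, plan)

    def test_identical_patients_identical_recommendations(self, plan, median_covariates,
                                                          right_base_lesion):
        r1 = recommend(median_covariates, right_base_lesion, plan)
        r2 = recommend(median_covariates, right_base_lesion, plan)
        assert r1 == r2

    def test_plan_json_roundtrip(self, plan, tmp_path):
        path = tmp_path / "plan.json"
        plan.to_json(path)
        assert LayerPlan.from_json(path) == plan
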