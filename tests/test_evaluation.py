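"""Scheme evaluation: detection, 2x2 tables, metrics, CIs and McNemar."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biopsyreduce import (
    ContingencyTable,
    CoreOutcomes,
    ValidationError,
    auc_ci,
    detect_at_k,
    evaluate_schemes,
    mcnemar_exact,
    metrics_from_table,
    tabulate_scheme,
)

RANKING = list(range(1, 13))

# printed layer-1 reference values: k -> (tp, sens%, npv%, acc%, auc)
LAYER1_PRINTED = {
    1: (17, 48.57, 82.86, 85.25, 0.743),
    2: (25, 71.43, 89.69, 91.80, 0.857),
    4: (27, 77.14, 91.58, 93.44, 0.886),
    5: (28, 80.00, 92.55, 94.26, 0.900),
    6: (30, 85.71, 94.57, 95.90, 0.929),
    7: (31, 88.57, 95.60, 96.72, 0.943),
    9: (34, 97.14, 98.86, 99.18, 0.986),
    10: (35, 100.0, 100.0, 100.0, 1.000),
    11: (35, 100.0, 100.0, 100.0, 1.000),
}


def _single_positive(position, grade=2):
    flags = [False] * 12
    isup = [0] * 12
    flags[position - 1] = True
    isup[position - 1] = grade
    return CoreOutcomes(positive=tuple(flags), isup=tuple(isup))


class TestDetectAtK:
    def test_all_benign_never_detected(self):
        benign = CoreOutcomes(positive=(False,) * 12)
        assert not any(detect_at_k(benign, RANKING, k) for k in range(1, 13))

    def test_ninth_ranked_positive_needs_nine_cores(self):
        outcomes = _single_positive(9)
        assert not detect_at_k(outcomes, RANKING, 8)
        assert detect_at_k(outcomes, RANKING, 9)
        assert detect_at_k(outcomes, RANKING, 12)

    def test_grade_threshold_filters_insignificant_cancer(self):
        outcomes = _single_positive(1, grade=1)
        assert detect_at_k(outcomes, RANKING, 12, grade_threshold=1)
        assert not any(detect_at_k(outcomes, RANKING, k, grade_threshold=2) for k in range(1, 13))

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="k must be"):
            detect_at_k(_single_positive(1), RANKING, 13)

    def test_threshold_without_grades_rejected(self):
        ungraded = CoreOutcomes(positive=(True,) + (False,) * 11)
        with pytest.raises(ValidationError, match="ISUP"):
            detect_at_k(ungraded, RANKING, 1, grade_threshold=2)


class TestTabulate:
    def test_layer1_fixture_at_one_core(self, layer1_fixture):
        t = tabulate_scheme(layer1_fixture, 1)
        assert (t.tp, t.fn, t.tn, t.fp) == (17, 18, 87, 0)

    def test_reference_agrees_with_itself(self, layer1_fixture):
        t = tabulate_scheme(layer1_fixture, 12)
        assert (t.tp, t.fn, t.tn, t.fp) == (35, 0, 87, 0)

    def test_single_negative_patient(self):
        benign = CoreOutcomes(positive=(False,) * 12)
        t = tabulate_scheme([(benign, RANKING)], 5)
        assert (t.tp, t.fn, t.tn, t.fp) == (0, 0, 1, 0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            tabulate_scheme([], 1)


class TestMetrics:
    @pytest.mark.parametrize("k", sorted(LAYER1_PRINTED))
    def test_layer1_metrics_match_printed_values(self, layer1_fixture, k):
        tp, sens, npv, acc, auc = LAYER1_PRINTED[k]
        m = metrics_from_table(tabulate_scheme(layer1_fixture, k), k=k)
        assert m.table.tp == tp
        assert round(100 * m.sensitivity, 2) == pytest.approx(sens, abs=0.005)
        assert round(100 * m.npv, 2) == pytest.approx(npv, abs=0.005)
        assert round(100 * m.accuracy, 2) == pytest.approx(acc, abs=0.005)
        assert round(m.auc, 3) == pytest.approx(auc, abs=0.0005)

    def test_no_reference_positives_rejected(self):
        with pytest.raises(ValidationError, match="sensitivity"):
            metrics_from_table(ContingencyTable(tp=0, fn=0, tn=5, fp=0))

    def test_nested_scheme_auc_identity(self, layer1_fixture):
        for k in range(1, 13):
            m = metrics_from_table(tabulate_scheme(layer1_fixture, k), k=k)
            assert m.table.fp == 0
            assert m.specificity == 1.0
            assert m.auc == (1.0 + m.sensitivity) / 2.0


class TestAucCi:
    def test_hanley_mcneil_nine_core_row(self):
        lo, hi = auc_ci(ContingencyTable(tp=34, fn=1, tn=87, fp=0))
        assert lo == pytest.approx(0.958, abs=1e-3)
        assert hi == 1.0

    def test_hanley_mcneil_one_core_row_near_printed(self):
        lo, hi = auc_ci(ContingencyTable(tp=17, fn=18, tn=87, fp=0))
        assert lo == pytest.approx(0.639, abs=1e-3)
        assert hi == pytest.approx(0.847, abs=1e-3)
        # printed interval (0.631, 0.855) is within 0.01 of both endpoints
        assert abs(lo - 0.631) < 0.01 and abs(hi - 0.855) < 0.01

    def test_perfect_table_upper_bound_is_one(self):
        lo, hi = auc_ci(ContingencyTable(tp=35, fn=0, tn=87, fp=0))
        assert hi == 1.0 and lo == 1.0

    def test_wald_halfsum_agrees_in_order_of_magnitude(self):
        table = ContingencyTable(tp=28, fn=7, tn=87, fp=0)
        hm = auc_ci(table, method="hanley_mcneil")
        wald = auc_ci(table, method="wald_halfsum")
        assert abs(hm[0] - wald[0]) < 0.05

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValidationError):
            auc_ci(ContingencyTable(tp=0, fn=0, tn=10, fp=0))


class TestMcnemar:
    @pytest.mark.parametrize("b,c,expected", [
        (0, 4, 0.125),
        (0, 1, 1.0),
        (3, 5, 0.7265625),  # 2 * sum_{i<=3} C(8,i) / 2^8
        (0, 0, 1.0),
        (0, 5, 0.0625),
    ])
    def test_exact_values(self, b, c, expected):
        assert mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-9)

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(0, 4), (2, 9), (5, 5), (1, 12), (7, 3)]:
            table = [[0, b], [c, 0]]
            expected = sm_mcnemar(table, exact=True).pvalue
            assert mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 25), st.integers(0, 25))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_equal_counts(self, b, c):
        assert mcnemar_exact(b, c) == mcnemar_exact(c, b)
        if b == c:
            assert mcnemar_exact(b, c) == 1.0
        assert 0.0 < mcnemar_exact(b, c) <= 1.0

    def test_large_counts_use_chisquare_fallback(self):
        p = mcnemar_exact(10, 20)
        from scipy import stats

        assert p == pytest.approx(stats.chi2.sf((abs(10 - 20) - 1) ** 2 / 30, 1))


class TestEvaluateSchemes:
    def test_monotone_in_k(self, layer1_fixture):
        series = evaluate_schemes(layer1_fixture)
        sens = [m.sensitivity for m in series]
        acc = [m.accuracy for m in series]
        auc = [m.auc for m in series]
        assert sens == sorted(sens) and acc == sorted(acc) and auc == sorted(auc)
        assert series[-1].sensitivity == 1.0 and series[-1].auc == 1.0

    def test_mcnemar_column_matches_printed_rows(self, layer1_fixture):
        series = {m.k: m for m in evaluate_schemes(layer1_fixture)}
        assert series[7].mcnemar_p == pytest.approx(0.125)
        assert series[9].mcnemar_p == pytest.approx(1.0)
        assert series[6].mcnemar_p == pytest.approx(0.0625, abs=5e-4)

    def test_agrees_with_bruteforce_patient_flags(self, layer1_fixture):
        rng_k = [1, 5, 9]
        for k in rng_k:
            m = metrics_from_table(tabulate_scheme(layer1_fixture, k), k=k)
            ref = [any(o.positive) for o, r in layer1_fixture]
            red = [any(o.positive[c - 1] for c in r[:k]) for o, r in layer1_fixture]
            tp = sum(a and b for a, b in zip(ref, red))
            tn = sum((not a) and (not b) for a, b in zip(ref, red))
            assert m.table.tp == tp and m.table.tn == tn
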