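"""Accuracy measures, exact intervals, kappa, and the paired-comparison chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from afscreen.accuracy import (
    ConfusionTable,
    DichotomyPolicy,
    UndefinedMeasureError,
    accuracy,
    bonferroni,
    build_confusion,
    cochran_q,
    cohens_kappa,
    dichotomize,
    exact_binomial_ci,
    false_positive_rate,
    mcnemar_test,
    ppv_and_fdr,
    sensitivity,
    specificity,
    table2_report,
)
from afscreen.calls import AF, SR, UNCLASSIFIED, UNREADABLE

# 2x2 tables reconstructed from the reference screening programme's marginal
# counts (26 reference AF, 39 device AF calls, 65 pulse AF calls, ...)
DEVICE_CT = ConfusionTable(tp=24, fp=15, fn=2, tn=557, n_excluded=6)
PULSE_CT = ConfusionTable(tp=20, fp=45, fn=6, tn=526, n_excluded=7)


class TestDichotomize:
    def test_default_partition(self):
        assert dichotomize(AF) == "positive"
        assert dichotomize(SR) == "negative"
        assert dichotomize(UNCLASSIFIED) == "negative"
        assert dichotomize(UNREADABLE) == "excluded"

    def test_published_tables_policy_excludes_nothing(self):
        pol = DichotomyPolicy.published_tables()
        assert dichotomize(UNREADABLE, pol) == "negative"

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            dichotomize("POSSIBLE_AF")

    def test_non_partition_rejected(self):
        with pytest.raises(ValueError):
            DichotomyPolicy(positive=frozenset({AF, SR}), negative=frozenset({SR, UNCLASSIFIED}),
                            excluded=frozenset({UNREADABLE}))


class TestBuildConfusion:
    def test_perfect_agreement(self):
        calls = [AF, SR, SR, UNCLASSIFIED]
        ct = build_confusion(calls, calls)
        assert (ct.fp, ct.fn) == (0, 0)
        assert ct.n_effective == 4

    def test_pairwise_exclusion_drops_either_side(self):
        index = [AF, UNREADABLE, SR]
        ref = [AF, SR, UNREADABLE]
        ct = build_confusion(index, ref)
        assert ct.n_effective == 1 and ct.n_excluded == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_confusion([AF], [AF, SR])

    def test_reference_study_device_counts(self, study_df):
        ct = build_confusion(study_df["call_device"], study_df["call_cardiologist"])
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (24, 15, 2, 557)
        assert ct.n_effective == 598


class TestProportionMeasures:
    @pytest.mark.parametrize(
        "measure,ct,expected_pct",
        [
            (sensitivity, DEVICE_CT, 92.3),
            (sensitivity, PULSE_CT, 76.9),
            (specificity, DEVICE_CT, 97.4),
            (accuracy, DEVICE_CT, 97.2),
            (lambda ct: ppv_and_fdr(ct)[1], DEVICE_CT, 38.5),
            (lambda ct: ppv_and_fdr(ct)[1], PULSE_CT, 69.2),
            (false_positive_rate, DEVICE_CT, 2.6),
        ],
    )
    def test_point_estimates_match_printed_values(self, measure, ct, expected_pct):
        assert round(100 * measure(ct).value, 1) == expected_pct

    def test_ppv_fdr_complementarity(self):
        ppv, fdr = ppv_and_fdr(DEVICE_CT)
        assert math.isclose(ppv.value + fdr.value, 1.0)

    def test_specificity_fpr_complementarity(self):
        assert math.isclose(
            specificity(DEVICE_CT).value + false_positive_rate(DEVICE_CT).value, 1.0
        )

    def test_undefined_denominators_raise(self):
        empty_pos = ConfusionTable(tp=0, fp=0, fn=0, tn=10)
        with pytest.raises(UndefinedMeasureError):
            sensitivity(empty_pos)
        with pytest.raises(UndefinedMeasureError):
            ppv_and_fdr(empty_pos)

    def test_degenerate_extremes(self):
        ct = ConfusionTable(tp=5, fp=0, fn=0, tn=5)
        assert sensitivity(ct).value == 1.0
        assert ppv_and_fdr(ct)[1].value == 0.0
        assert false_positive_rate(ct).value == 0.0


class TestExactBinomialCI:
    def test_printed_interval_for_24_of_26(self):
        lo, hi = exact_binomial_ci(24, 26)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (74.9, 99.1)

    def test_boundary_cases_exact(self):
        assert exact_binomial_ci(0, 10)[0] == 0.0
        assert exact_binomial_ci(10, 10)[1] == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)
        with pytest.raises(ValueError):
            exact_binomial_ci(1, 4, level=1.0)

    @given(x=st.integers(0, 40), n=st.integers(1, 40))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_interval_contains_point_estimate(self, x, n):
        x = min(x, n)
        lo, hi = exact_binomial_ci(x, n)
        assert lo <= x / n <= hi


class TestCohensKappa:
    def test_perfect_agreement_is_one(self):
        assert cohens_kappa(ConfusionTable(10, 0, 0, 10)).value == 1.0

    def test_device_table_matches_printed_kappa(self):
        assert round(cohens_kappa(DEVICE_CT).value, 2) == 0.72

    def test_independent_margins_give_zero(self):
        # margins 30/70 x 30/70 with counts proportional to the products
        assert cohens_kappa(ConfusionTable(tp=9, fp=21, fn=21, tn=49)).value == pytest.approx(0.0)

    def test_direct_formula_oracle(self):
        ct = ConfusionTable(tp=13, fp=7, fn=4, tn=31)
        n = ct.n_effective
        p_o = (ct.tp + ct.tn) / n
        p_e = ((ct.tp + ct.fp) * (ct.tp + ct.fn) + (ct.fn + ct.tn) * (ct.fp + ct.tn)) / n**2
        assert cohens_kappa(ct).value == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_degenerate_marginals_raise(self):
        with pytest.raises(UndefinedMeasureError):
            cohens_kappa(ConfusionTable(tp=10, fp=0, fn=0, tn=0))

    def test_against_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        ct = ConfusionTable(tp=24, fp=15, fn=2, tn=557)
        table = np.array([[ct.tp, ct.fn], [ct.fp, ct.tn]])
        assert cohens_kappa(ct).value == pytest.approx(float(sm_kappa(table).kappa))


class TestMcNemar:
    def test_symmetric_discordance_gives_p_one(self):
        res = mcnemar_test([True] * 8 + [False] * 8, [False] * 8 + [True] * 8)
        assert (res.b, res.c) == (8, 8)
        assert res.p_value == 1.0

    def test_one_sided_discordance_closed_form(self):
        a = [True] * 10 + [True] * 5
        b = [False] * 10 + [True] * 5
        res = mcnemar_test(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 * 0.5**10)

    def test_identical_vectors_no_discordants(self):
        flags = [True, False, True]
        res = mcnemar_test(flags, flags)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_branch_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(0)
        a = rng.random(300) < 0.9
        b = rng.random(300) < 0.75
        res = mcnemar_test(a, b)
        assert res.method == "chi2"
        table = [[int((a & b).sum()), int((a & ~b).sum())], [int((~a & b).sum()), int((~a & ~b).sum())]]
        sm = sm_mcnemar(table, exact=False, correction=True)
        assert res.statistic == pytest.approx(float(sm.statistic))
        assert res.p_value == pytest.approx(float(sm.pvalue))

    def test_exact_branch_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        a = [True] * 7 + [False] * 3 + [True] * 20
        b = [False] * 7 + [True] * 3 + [True] * 20
        res = mcnemar_test(a, b)
        sm = sm_mcnemar([[20, 7], [3, 0]], exact=True)
        assert res.p_value == pytest.approx(float(sm.pvalue))


class TestCochranQ:
    def test_all_correct_gives_zero(self):
        res = cochran_q(np.ones((10, 3)))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_k2_equals_uncorrected_mcnemar(self):
        rng = np.random.default_rng(1)
        x = (rng.random((60, 2)) < 0.7).astype(int)
        q = cochran_q(x)
        b = int((x[:, 0] & ~x[:, 1].astype(bool)).sum())
        c = int((~x[:, 0].astype(bool) & x[:, 1].astype(bool)).sum())
        expected = (b - c) ** 2 / (b + c)
        assert q.statistic == pytest.approx(expected)

    def test_brute_force_defining_formula(self):
        rng = np.random.default_rng(2)
        x = (rng.random((20, 3)) < 0.6).astype(float)
        res = cochran_q(x)
        n, k = x.shape
        col = x.sum(axis=0)
        row = x.sum(axis=1)
        q_direct = (k - 1) * (k * (col**2).sum() - col.sum() ** 2) / (k * row.sum() - (row**2).sum())
        assert res.statistic == pytest.approx(q_direct)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(q_direct, k - 1)))

    def test_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import cochrans_q

        rng = np.random.default_rng(3)
        x = (rng.random((50, 4)) < 0.8).astype(int)
        res = cochran_q(x)
        sm = cochrans_q(x, return_object=True)
        assert res.statistic == pytest.approx(float(sm.statistic))
        assert res.p_value == pytest.approx(float(sm.pvalue))

    def test_rejects_missing_flags(self):
        with pytest.raises(ValueError):
            cochran_q(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni([0.01, 0.02, 0.04], 3) == [0.03, 0.06, 0.12]
        assert bonferroni([0.5], 3) == [1.0]
        assert bonferroni([]) == []

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 2)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


class TestTable2Report:
    def test_error_free_raters_give_all_ones(self):
        from afscreen.cohort import CohortConfig, RaterErrorModel, generate_cohort, simulate_calls

        cfg = CohortConfig(n_participants=2000, seed=21)
        df = simulate_calls(generate_cohort(cfg), RaterErrorModel.error_free(), seed=21)
        rows, _ = table2_report(df)
        for r in rows.values():
            assert r.sensitivity.value == 1.0
            assert r.specificity.value == 1.0
            assert r.kappa.value == 1.0

    def test_pairwise_denominators_on_reference_cohort(self, study_df):
        rows, _ = table2_report(study_df)
        assert rows["device"].n_effective == 598
        assert rows["pulse"].n_effective == 597
        assert rows["pharmacist"].n_effective == 597

    def test_adjusted_p_values_capped_and_scaled(self, study_df):
        _, comp = table2_report(study_df)
        assert len(comp.pairwise) == 3
        for p in comp.pairwise:
            assert p.bonferroni_adjusted_p == pytest.approx(min(1.0, 3 * p.raw_p))

    def test_single_participant_does_not_crash(self, study_df):
        rows, _ = table2_report(study_df.iloc[[0]])
        r = rows["device"]  # one AF participant: sensitivity 1/1, the rest undefined
        assert r.sensitivity.ci[0] < 0.1 and r.sensitivity.ci[1] == 1.0
        assert r.specificity is None and r.kappa is None
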