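"""Cohort rules, adjudication, comparison statistics and ROC analysis."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pmapdose import (
    PatientRecord,
    PlanMetrics,
    adjudicate_success,
    assign_cohort,
    compare_plan_sets,
    reclassification_summary,
    roc_dice_vs_success,
)


def panel(ptv95, dmean_pmap_bed, **overrides):
    """A plan panel with compliant organ-at-risk values unless overridden."""
    values = {
        "PTV95": ptv95,
        "Pmap_Dmean_BED": dmean_pmap_bed,
        "2Lungs_V20": 25.0,
        "SpinalCord_Dmax": 38.0,
        "Heart_V40": 4.0,
        "2Lungs_Dmean": 15.0,
        "LungH_V5": 65.0,
    }
    values.update(overrides)
    return PlanMetrics(values)


def record(ptv95_i, dmean_i, ptv95_o, dmean_o, prob=0.9, **opt_overrides):
    return PatientRecord(
        id="T",
        metrics_initial=panel(ptv95_i, dmean_i),
        metrics_optimized=panel(ptv95_o, dmean_o, **opt_overrides),
        prob_initial=prob,
    )


class TestAssignCohort:
    def test_exhaustive_truth_table(self):
        for hi_prob, hi_dmean, success in itertools.product([False, True], repeat=3):
            prob = 0.5 if hi_prob else 0.05
            dmean = 36.0 if hi_dmean else 20.0
            got = assign_cohort(prob, dmean, success)
            if not hi_prob:
                expected = "excluded"
            elif not hi_dmean:
                expected = "3"
            else:
                expected = "1" if success else "2"
            assert got == expected

    def test_reported_style_cases(self):
        assert assign_cohort(0.94, 36.6, True) == "1"
        assert assign_cohort(0.10, 14.6, False) == "3"
        assert assign_cohort(0.05, 40.0, True) == "excluded"

    def test_inclusive_boundaries(self):
        assert assign_cohort(0.08, 30.3, False) == "2"
        assert assign_cohort(0.08, 30.2999, False) == "3"
        assert assign_cohort(0.0799, 50.0, True) == "excluded"


class TestAdjudicateSuccess:
    def test_successful_worked_example(self):
        # high-start patient brought under threshold with improved coverage
        success, reasons = adjudicate_success(record(96.4, 36.5, 97.7, 24.8))
        assert success and reasons == []

    def test_unsuccessful_worked_example_lists_both_failures(self):
        success, reasons = adjudicate_success(record(93.6, 60.2, 68.3, 44.2))
        assert not success
        text = " ".join(reasons)
        assert "coverage" in text
        assert "Pmap" in text

    def test_exact_threshold_on_optimized_plan_fails(self):
        success, reasons = adjudicate_success(record(96.0, 40.0, 96.0, 30.3))
        assert not success and any("Pmap" in r for r in reasons)

    def test_low_start_twenty_percent_rule(self):
        ok, _ = adjudicate_success(record(96.0, 14.6, 96.0, 10.3))  # 29.5% drop
        assert ok
        bad, reasons = adjudicate_success(record(96.0, 14.6, 96.0, 13.0))  # 11% drop
        assert not bad and any("reduction" in r for r in reasons)

    def test_oar_violation_blocks_success(self):
        success, reasons = adjudicate_success(
            record(96.0, 40.0, 96.0, 25.0, **{"2Lungs_V20": 40.0})
        )
        assert not success and any("2Lungs_V20" in r for r in reasons)

    def test_coverage_tolerance_below_floor(self):
        # started below 95%: only the one-point tolerance applies
        ok, _ = adjudicate_success(record(93.0, 40.0, 92.2, 25.0))
        assert ok
        bad, _ = adjudicate_success(record(93.0, 40.0, 91.5, 25.0))
        assert not bad

    def test_failure_implies_reasons_and_success_monotone_in_dmean(self):
        for dmean_o in np.linspace(45.0, 5.0, 12):
            success, reasons = adjudicate_success(record(96.0, 40.0, 96.0, dmean_o))
            assert success == (len(reasons) == 0)
        flags = [
            adjudicate_success(record(96.0, 40.0, 96.0, d))[0]
            for d in np.linspace(45.0, 5.0, 12)
        ]
        # once successful, lowering the optimized Pmap dose further never hurts
        assert flags == sorted(flags)

    def test_missing_metrics_rejected(self):
        with pytest.raises(ValueError, match="both plans"):
            adjudicate_success(PatientRecord(id="X", metrics_initial=panel(96, 30)))


class TestComparePlanSets:
    def test_identical_arms_not_significant(self, rng):
        plans = [panel(95.0 + i * 0.1, 30.0 + i) for i in range(10)]
        rows = compare_plan_sets(plans, plans)
        for row in rows:
            assert row.p_value >= 0.9
            assert row.ci_initial[0] <= row.mean_initial <= row.ci_initial[1]

    def test_shifted_normal_detected_with_t_test(self, rng):
        a = rng.normal(30.0, 1.0, 50)
        b = rng.normal(33.0, 1.0, 50)  # 3 sigma shift
        rows = compare_plan_sets(
            [panel(95, v) for v in a], [panel(95, v) for v in b]
        )
        row = {r.metric: r for r in rows}["Pmap_Dmean_BED"]
        assert row.p_value < 0.001
        assert row.test_used == "t"

    def test_heavy_tails_fall_back_to_mann_whitney(self, rng):
        a = stats.cauchy.rvs(loc=30, size=40, random_state=rng)
        b = stats.cauchy.rvs(loc=30, size=40, random_state=rng)
        a, b = np.abs(a), np.abs(b)
        rows = compare_plan_sets(
            [panel(95, v) for v in a], [panel(95, v) for v in b]
        )
        row = {r.metric: r for r in rows}["Pmap_Dmean_BED"]
        assert row.test_used == "mann_whitney"

    def test_small_arms_rejected(self):
        plans = [panel(95, 30)] * 2
        with pytest.raises(ValueError, match="at least 3"):
            compare_plan_sets(plans, plans)


def prob_record(i, p_ini, p_opt):
    return PatientRecord(id=f"P{i}", prob_initial=p_ini, prob_optimized=p_opt)


class TestReclassification:
    def test_unchanged_probabilities(self):
        recs = [prob_record(i, 0.5, 0.5) for i in range(10)]
        s = reclassification_summary(recs)
        assert s.high_to_low == 0 and s.low_to_high == 0
        assert s.p_mcnemar == 1.0

    def test_eight_of_twentyfour_reclassified(self):
        # 8 high->low, 16 stay high: one third reclassified at low risk
        recs = [prob_record(i, 0.9, 0.05) for i in range(8)]
        recs += [prob_record(8 + i, 0.9, 0.9) for i in range(16)]
        s = reclassification_summary(recs)
        assert s.high_to_low == 8
        assert s.fraction_reclassified_low == pytest.approx(8 / 24)
        assert s.p_mcnemar < 0.01

    def test_counts_conserve_initial_high(self, cohort100):
        included = [r for r in cohort100 if r.cohort in ("1", "2", "3")]
        s = reclassification_summary(included, seed=4)
        stays_high = s.high_optimized - s.low_to_high
        assert s.high_initial == stays_high + s.high_to_low

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            reclassification_summary([])


def pairwise_auc(scores, labels):
    """All-pairs Mann-Whitney AUC with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        dice = np.array([0.3, 0.4, 0.5, 0.0, 0.05, 0.1])
        success = np.array([False, False, False, True, True, True])
        res = roc_dice_vs_success(dice, success)
        assert res.auc == 1.0
        assert 0.1 < res.youden_cutoff <= 0.3
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_auc_equals_pairwise_statistic(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 40))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            res = roc_dice_vs_success(scores, labels == 0)
            assert res.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    def test_youden_cutoff_matches_brute_force(self, rng):
        scores = rng.random(60)
        success = rng.random(60) < 0.5
        if success.all() or not success.any():
            success[:2] = [True, False]
        res = roc_dice_vs_success(scores, success)
        y = (~success).astype(int)
        best_j = -np.inf
        for c in np.unique(scores):
            sens = np.mean(scores[y == 1] >= c)
            spec = np.mean(scores[y == 0] < c)
            best_j = max(best_j, sens + spec - 1)
        got_sens = np.mean(scores[y == 1] >= res.youden_cutoff)
        got_spec = np.mean(scores[y == 0] < res.youden_cutoff)
        assert got_sens + got_spec - 1 == pytest.approx(best_j, abs=1e-12)
        assert res.sensitivity == pytest.approx(got_sens)
        assert res.specificity == pytest.approx(got_spec)

    def test_null_scores_give_chance_auc(self, rng):
        scores = rng.random(200)
        success = rng.random(200) < 0.5
        res = roc_dice_vs_success(scores, success)
        assert 0.42 <= res.auc <= 0.58

    def test_invariant_under_monotone_score_transform(self, rng):
        scores = rng.random(50)
        success = rng.random(50) < 0.6
        if success.all() or not success.any():
            success[:2] = [True, False]
        a = roc_dice_vs_success(scores, success).auc
        b = roc_dice_vs_success(np.sqrt(scores), success).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_dice_vs_success([0.1, 0.2], [True, True])
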