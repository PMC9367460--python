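"""Cohort assignment, optimization adjudication and comparison statistics.

The study design this module implements: patients at high predicted risk of
acute pulmonary toxicity (probability >= 8%) have their plan re-optimised
with an added constraint on the Pmap sub-region (mean BED dose < 30.3 Gy).
Patients split into three cohorts on the initial plan — Cohort 1/2 started
at or above the 30.3 Gy threshold (1 if the re-optimisation succeeded, 2 if
not); Cohort 3 started below it, where success instead means a >= 20%
relative reduction of the Pmap mean dose.  In both cases success also
requires that target coverage is maintained and (for Cohorts 1/2) that the
usual organ-at-risk constraints still hold.

Statistics: plan-set panels are compared arm-vs-arm with a two-sample t-test
when both arms pass Shapiro-Wilk normality at alpha = 0.05, otherwise with
Mann-Whitney U; the reclassification summary additionally reports properly
paired tests (exact McNemar on class changes, Wilcoxon signed-rank on
probabilities).  The DICE overlap between PTV and Pmap is evaluated as a
predictor of optimisation *failure* via ROC, with a Youden-optimal cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import PlanMetrics
from .risk import DMEAN_THRESHOLD_GY, PROB_THRESHOLD, ClinicalFeatures

__all__ = [
    "PatientRecord",
    "OARConstraint",
    "ConstraintSet",
    "DEFAULT_CONSTRAINTS",
    "ComparisonRow",
    "RocResult",
    "ReclassificationSummary",
    "assign_cohort",
    "adjudicate_success",
    "compare_plan_sets",
    "reclassification_summary",
    "roc_dice_vs_success",
]


@dataclass(frozen=True)
class OARConstraint:
    """One organ-at-risk bound on a PlanMetrics key, e.g. 2Lungs_V20 <= 35."""

    metric: str
    bound: float
    direction: str = "<="

    def satisfied(self, metrics: PlanMetrics) -> bool:
        v = metrics[self.metric]
        return v <= self.bound if self.direction == "<=" else v >= self.bound

    def describe(self, metrics: PlanMetrics) -> str:
        return f"{self.metric} = {metrics[self.metric]:.2f} violates {self.direction} {self.bound}"


@dataclass
class ConstraintSet:
    """Success rules: Pmap threshold, coverage tolerance and OAR bounds.

    Coverage is "maintained" when the optimised PTV95 is at least
    ``min(ptv95_floor, initial PTV95 - ptv95_drop_tolerance)``: a plan that
    started below the nominal floor only has to stay within the tolerance of
    its own starting coverage.  The shipped OAR bounds are generic
    lung-radiotherapy constraints and fully overridable.
    """

    oar_constraints: tuple[OARConstraint, ...] = ()
    ptv95_floor: float = 95.0
    ptv95_drop_tolerance: float = 1.0
    dmean_threshold: float = DMEAN_THRESHOLD_GY
    reduction_fraction: float = 0.20

    def coverage_maintained(self, ptv95_initial: float, ptv95_optimized: float) -> bool:
        floor = min(self.ptv95_floor, ptv95_initial - self.ptv95_drop_tolerance)
        return ptv95_optimized >= floor


DEFAULT_CONSTRAINTS = ConstraintSet(
    oar_constraints=(
        OARConstraint("2Lungs_V20", 35.0),
        OARConstraint("SpinalCord_Dmax", 45.0),
        OARConstraint("Heart_V40", 30.0),
    )
)


@dataclass
class PatientRecord:
    """One patient's features, paired plan metrics, risk probabilities and labels."""

    id: str
    features: ClinicalFeatures | None = None
    metrics_initial: PlanMetrics | None = None
    metrics_optimized: PlanMetrics | None = None
    prob_initial: float | None = None
    prob_optimized: float | None = None
    dice_ptv_pmap: float | None = None
    apt_observed: int | None = None
    cohort: str | None = None
    success: bool | None = None
    failure_reasons: list[str] = field(default_factory=list)


def adjudicate_success(
    r: PatientRecord, c: ConstraintSet = DEFAULT_CONSTRAINTS
) -> tuple[bool, list[str]]:
    """Decide whether the re-optimisation succeeded, with explicit reasons.

    High-start rule (initial Pmap mean BED >= threshold): the optimised plan
    must bring the Pmap mean below the threshold, maintain coverage and meet
    every OAR constraint.  Low-start rule (already below threshold): the Pmap
    mean must drop by at least ``reduction_fraction`` relative, with coverage
    maintained.  ``reasons`` lists every violated criterion; it is empty iff
    the optimisation succeeded.
    """
    if r.metrics_initial is None or r.metrics_optimized is None:
        raise ValueError(f"patient {r.id}: both plans' metrics are required")
    ini, opt = r.metrics_initial, r.metrics_optimized
    reasons: list[str] = []
    if not c.coverage_maintained(ini.ptv95, opt.ptv95):
        floor = min(c.ptv95_floor, ini.ptv95 - c.ptv95_drop_tolerance)
        reasons.append(
            f"PTV coverage compromised: optimized PTV95 {opt.ptv95:.1f}% < {floor:.1f}%"
        )
    if ini.dmean_pmap_bed >= c.dmean_threshold:
        if opt.dmean_pmap_bed >= c.dmean_threshold:
            reasons.append(
                f"Pmap constraint unmet: optimized DMeanPmap {opt.dmean_pmap_bed:.1f} Gy "
                f">= {c.dmean_threshold} Gy"
            )
        for oc in c.oar_constraints:
            if not oc.satisfied(opt):
                reasons.append(f"OAR constraint unmet: {oc.describe(opt)}")
    else:
        if ini.dmean_pmap_bed > 0:
            drop = 1.0 - opt.dmean_pmap_bed / ini.dmean_pmap_bed
        else:
            drop = 0.0
        if drop < c.reduction_fraction:
            reasons.append(
                f"DMeanPmap reduction {100 * drop:.1f}% < {100 * c.reduction_fraction:.0f}%"
            )
    return (len(reasons) == 0, reasons)


def assign_cohort(
    prob_initial: float,
    dmean_pmap_initial: float,
    success: bool,
    *,
    prob_threshold: float = PROB_THRESHOLD,
    dmean_threshold: float = DMEAN_THRESHOLD_GY,
) -> str:
    """Cohort label from the initial-plan risk probability, Pmap dose and success.

    'excluded' below the probability threshold; '3' when the initial Pmap
    mean BED dose is already below the dose threshold; otherwise '1' on
    successful optimisation, '2' on failure.  All thresholds inclusive (>=).
    """
    if not (0 <= prob_initial <= 1):
        raise ValueError(f"prob_initial must be in [0, 1], got {prob_initial}")
    if prob_initial < prob_threshold:
        return "excluded"
    if dmean_pmap_initial < dmean_threshold:
        return "3"
    return "1" if success else "2"


def label_record(
    r: PatientRecord, c: ConstraintSet = DEFAULT_CONSTRAINTS
) -> PatientRecord:
    """Adjudicate success then assign the cohort, in place."""
    if r.prob_initial is None:
        raise ValueError(f"patient {r.id}: prob_initial missing")
    r.success, r.failure_reasons = adjudicate_success(r, c)
    r.cohort = assign_cohort(
        r.prob_initial,
        r.metrics_initial.dmean_pmap_bed,
        r.success,
        dmean_threshold=c.dmean_threshold,
    )
    return r


@dataclass(frozen=True)
class ComparisonRow:
    """One metric's arm-vs-arm comparison: means, CI95 bounds and the p-value."""

    metric: str
    mean_initial: float
    ci_initial: tuple[float, float]
    mean_optimized: float
    ci_optimized: tuple[float, float]
    p_value: float
    test_used: str


def _mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    m = float(np.mean(values))
    if len(values) < 2 or np.ptp(values) == 0:
        return m, (m, m)
    sem = stats.sem(values)
    lo, hi = stats.t.interval(level, len(values) - 1, loc=m, scale=sem)
    return m, (float(lo), float(hi))


def _is_normal(values: np.ndarray, alpha: float = 0.05) -> bool:
    # Shapiro-Wilk is undefined for constant samples; treat those as non-normal.
    if np.ptp(values) == 0:
        return False
    return stats.shapiro(values).pvalue > alpha


def compare_plan_sets(
    initial: Sequence[PlanMetrics], optimized: Sequence[PlanMetrics]
) -> list[ComparisonRow]:
    """Unpaired metric-by-metric comparison of two plan sets.

    Per metric: arm means with t-based CI95 and a two-sided p-value from a
    two-sample t-test when both arms pass Shapiro-Wilk normality (alpha 0.05),
    otherwise from Mann-Whitney U.  The test actually used is recorded per
    row.  The arms are compared unpaired even though the plans are paired —
    this mirrors published plan-comparison tables; see
    :func:`reclassification_summary` for the paired alternative.
    """
    if len(initial) < 3 or len(optimized) < 3:
        raise ValueError("compare_plan_sets needs at least 3 plans per arm")
    keys = list(initial[0].values)
    rows: list[ComparisonRow] = []
    for key in keys:
        a = np.asarray([m[key] for m in initial], dtype=float)
        b = np.asarray([m[key] for m in optimized], dtype=float)
        mean_a, ci_a = _mean_ci(a)
        mean_b, ci_b = _mean_ci(b)
        if _is_normal(a) and _is_normal(b):
            p = float(stats.ttest_ind(a, b).pvalue)
            test = "t"
        else:
            if np.ptp(np.concatenate([a, b])) == 0:
                p, test = 1.0, "mann_whitney"  # all values identical across arms
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                test = "mann_whitney"
        rows.append(ComparisonRow(key, mean_a, ci_a, mean_b, ci_b, p, test))
    return rows


def _median_ci_bootstrap(
    values: np.ndarray, rng: np.random.Generator, n_boot: int = 2000, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    med = float(np.median(values))
    if len(values) < 2:
        return med, (med, med)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boots = np.median(np.asarray(values)[idx], axis=1)
    alpha = (1 - level) / 2
    return med, (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha)))


@dataclass(frozen=True)
class ReclassificationSummary:
    """Risk-class transitions between the initial and optimised plans."""

    n: int
    high_initial: int
    high_optimized: int
    high_to_low: int
    low_to_high: int
    fraction_reclassified_low: float  # high->low over all records
    mean_prob_initial: float
    ci_mean_prob_initial: tuple[float, float]
    mean_prob_optimized: float
    ci_mean_prob_optimized: tuple[float, float]
    median_prob_initial: float
    ci_median_prob_initial: tuple[float, float]
    median_prob_optimized: float
    ci_median_prob_optimized: tuple[float, float]
    p_mcnemar: float
    p_wilcoxon: float


def reclassification_summary(
    records: Sequence[PatientRecord],
    threshold: float = PROB_THRESHOLD,
    *,
    seed: int = 0,
    n_boot: int = 2000,
) -> ReclassificationSummary:
    """Count high/low risk-class transitions and test the paired change.

    Class changes are tested with an exact McNemar test on the discordant
    pairs; the probability shift itself with a Wilcoxon signed-rank test.
    Median CI95s use a seeded percentile bootstrap (``n_boot`` resamples).
    """
    from statsmodels.stats.contingency_tables import mcnemar

    if not records:
        raise ValueError("reclassification_summary needs at least one record")
    p_ini = np.asarray([r.prob_initial for r in records], dtype=float)
    p_opt = np.asarray([r.prob_optimized for r in records], dtype=float)
    if np.any(~np.isfinite(p_ini)) or np.any(~np.isfinite(p_opt)):
        raise ValueError("every record needs both plan probabilities")
    hi_ini = p_ini >= threshold
    hi_opt = p_opt >= threshold
    table = np.array(
        [
            [np.sum(hi_ini & hi_opt), np.sum(hi_ini & ~hi_opt)],
            [np.sum(~hi_ini & hi_opt), np.sum(~hi_ini & ~hi_opt)],
        ]
    )
    p_mcnemar = float(mcnemar(table, exact=True).pvalue)
    diffs = p_opt - p_ini
    if np.all(diffs == 0):
        p_wilcoxon = 1.0
    else:
        p_wilcoxon = float(stats.wilcoxon(p_ini, p_opt).pvalue)
    rng = np.random.default_rng(seed)
    mean_i, ci_mean_i = _mean_ci(p_ini)
    mean_o, ci_mean_o = _mean_ci(p_opt)
    med_i, ci_med_i = _median_ci_bootstrap(p_ini, rng, n_boot)
    med_o, ci_med_o = _median_ci_bootstrap(p_opt, rng, n_boot)
    return ReclassificationSummary(
        n=len(records),
        high_initial=int(np.sum(hi_ini)),
        high_optimized=int(np.sum(hi_opt)),
        high_to_low=int(table[0, 1]),
        low_to_high=int(table[1, 0]),
        fraction_reclassified_low=float(table[0, 1] / len(records)),
        mean_prob_initial=mean_i,
        ci_mean_prob_initial=ci_mean_i,
        mean_prob_optimized=mean_o,
        ci_mean_prob_optimized=ci_mean_o,
        median_prob_initial=med_i,
        ci_median_prob_initial=ci_med_i,
        median_prob_optimized=med_o,
        ci_median_prob_optimized=ci_med_o,
        p_mcnemar=p_mcnemar,
        p_wilcoxon=p_wilcoxon,
    )


@dataclass(frozen=True)
class RocResult:
    """ROC of a score against a binary outcome, with the Youden-optimal cutoff.

    ``orientation`` records which class counts as positive; sensitivities and
    specificities refer to that orientation, and a case is called positive
    when its score is >= ``youden_cutoff``.
    """

    auc: float
    youden_cutoff: float
    sensitivity: float
    specificity: float
    orientation: str


def roc_dice_vs_success(
    dice_values: Sequence[float], success_flags: Sequence[bool]
) -> RocResult:
    """ROC of the PTV-Pmap DICE overlap as a predictor of optimisation failure.

    A large overlap between the target and the sub-region leaves the
    optimiser no room, so *failure* is the positive class and higher DICE
    means more positive.  The cutoff maximises the Youden index
    J = sensitivity + specificity - 1 (ties broken toward the smallest
    cutoff, i.e. highest sensitivity).
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(dice_values, dtype=float)
    success = np.asarray(success_flags, dtype=bool)
    if scores.shape != success.shape:
        raise ValueError("dice_values and success_flags lengths differ")
    y = (~success).astype(int)  # positive class: failure
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both successful and unsuccessful cases")
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.max(np.nonzero(j == j.max())[0]))  # last index = smallest threshold
    cutoff = float(thresholds[best])
    if np.isinf(cutoff):  # sklearn's sentinel above the max score
        cutoff = float(scores.max())
    return RocResult(
        auc=auc,
        youden_cutoff=cutoff,
        sensitivity=float(tpr[best]),
        specificity=float(1 - fpr[best]),
        orientation="failure_positive_high_dice",
    )


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (one row per patient) for reporting."""
    rows = []
    for r in records:
        row: dict[str, object] = {"id": r.id}
        if r.features is not None:
            row.update(
                smoking_status=r.features.smoking_status,
                copd=r.features.copd,
                mevs=r.features.mevs,
                ajcc_stage=r.features.ajcc_stage,
            )
        if r.metrics_initial is not None:
            row.update({f"initial_{k}": v for k, v in r.metrics_initial.values.items()})
        if r.metrics_optimized is not None:
            row.update({f"optimized_{k}": v for k, v in r.metrics_optimized.values.items()})
        row.update(
            prob_initial=r.prob_initial,
            prob_optimized=r.prob_optimized,
            dice_ptv_pmap=r.dice_ptv_pmap,
            apt_observed=r.apt_observed,
            cohort=r.cohort,
            success=r.success,
            failure_reasons="; ".join(r.failure_reasons),
        )
        rows.append(row)
    return pd.DataFrame(rows)
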