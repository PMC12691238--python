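"""Dyslipidemia classification and diagnostic concordance against direct LDL-C.

The screening rule labels a subject dyslipidemic when LDL-C exceeds
100 mg/dL (strict), or triglycerides reach an age-stratified cutoff
(>= 100 mg/dL under 10 years, >= 130 mg/dL from 10 to 18 years).  The rule
applies to ages 2-18; younger or older subjects are excluded, not labelled.

The concordance report compares a calculated-LDL method (prediction)
against the direct assay (truth) through the full caret-style metric set:
accuracy with exact binomial CI, the no-information rate and the one-sided
binomial test of accuracy against it, Cohen's kappa, sensitivity,
specificity, predictive values, detection rate/prevalence, balanced
accuracy, and the continuity-corrected McNemar test on the discordant cells.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .lipids import LdlMethod, LipidPanel, friedewald_ldl, sampson_ldl

__all__ = [
    "DyslipidemiaRule",
    "AgeOutOfRangeError",
    "ConfusionMatrix",
    "DiagnosticReport",
    "classify_dyslipidemia",
    "confusion",
    "diagnostic_metrics",
    "evaluate_method",
]


class AgeOutOfRangeError(ValueError):
    """Subject age falls outside the rule's window: excluded, not classified."""


@dataclass(frozen=True)
class DyslipidemiaRule:
    """Age-stratified pediatric dyslipidemia cutoffs, all in mg/dL.

    LDL is compared strictly (``>``); the TG cutoffs are inclusive (``>=``),
    with the young cutoff applying below ``age_split`` years.
    """

    ldl_cutoff: float = 100.0
    tg_cutoff_young: float = 100.0
    tg_cutoff_old: float = 130.0
    age_split: float = 10.0
    age_min: float = 2.0
    age_max: float = 18.0

    def __post_init__(self) -> None:
        if min(self.ldl_cutoff, self.tg_cutoff_young, self.tg_cutoff_old) <= 0:
            raise ValueError("all cutoffs must be > 0")
        if not (self.age_min < self.age_split < self.age_max):
            raise ValueError(
                f"require age_min < age_split < age_max, got "
                f"{self.age_min}, {self.age_split}, {self.age_max}"
            )


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; prediction = calculated method, truth = direct method."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one subject")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_text(self) -> str:
        """2x2 table, rows = prediction, columns = truth."""
        rows = [
            ("", "True Dyslipidemia", "True No Dyslipidemia"),
            ("Dyslipidemia", str(self.tp), str(self.fp)),
            ("No dyslipidemia", str(self.fn), str(self.tn)),
        ]
        widths = [max(len(r[i]) for r in rows) for i in range(3)]
        return "\n".join(
            "  ".join(cell.rjust(w) for cell, w in zip(r, widths)) for r in rows
        )


@dataclass(frozen=True)
class DiagnosticReport:
    """Full diagnostic-performance metric set for one calculated-LDL method.

    Proportions are on [0, 1]; undefined metrics (empty margins) are NaN,
    never silently 0.
    """

    accuracy: float
    accuracy_ci95: tuple[float, float]
    nir: float
    p_accuracy_gt_nir: float
    kappa: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    detection_rate: float
    detection_prevalence: float
    balanced_accuracy: float
    mcnemar_statistic: float
    mcnemar_p: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["accuracy_ci95"] = list(self.accuracy_ci95)
        return d


def classify_dyslipidemia(
    ldl: float,
    tg: float,
    age_years: float,
    rule: DyslipidemiaRule = DyslipidemiaRule(),
) -> bool:
    """Apply the age-stratified dyslipidemia rule to one subject.

    Raises :class:`AgeOutOfRangeError` outside [age_min, age_max]; callers
    evaluating cohorts exclude (and count) such subjects upstream.
    """
    if not (rule.age_min <= age_years <= rule.age_max):
        raise AgeOutOfRangeError(
            f"age {age_years} outside rule window [{rule.age_min}, {rule.age_max}]"
        )
    if ldl > rule.ldl_cutoff:
        return True
    if age_years < rule.age_split:
        return tg >= rule.tg_cutoff_young
    return tg >= rule.tg_cutoff_old


def confusion(pred: Sequence[bool], truth: Sequence[bool]) -> ConfusionMatrix:
    """Tally a prediction/truth label pair into a 2x2 confusion matrix."""
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(f"pred and truth must be 1-D and equal length, got {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("need at least one subject")
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticReport:
    """Compute the full diagnostic report from a 2x2 confusion matrix.

    Accuracy carries an exact (Clopper-Pearson) 95% CI.  The no-information
    rate (NIR) is the larger truth-class fraction, and ``p_accuracy_gt_nir``
    is the one-sided exact binomial tail P(X >= correct | n, p = NIR).
    Kappa uses the usual row-by-column chance agreement.  McNemar is the
    continuity-corrected statistic (|fp - fn| - 1)^2 / (fp + fn) against
    chi-square with 1 df, with p = 1 when there are no discordant pairs.
    """
    n = cm.total
    correct = cm.tp + cm.tn
    truth_pos = cm.tp + cm.fn
    truth_neg = cm.tn + cm.fp
    pred_pos = cm.tp + cm.fp
    pred_neg = cm.tn + cm.fn

    accuracy = correct / n
    ci = stats.binomtest(correct, n).proportion_ci(confidence_level=0.95, method="exact")
    nir = max(truth_pos, truth_neg) / n
    # P(X >= correct) for X ~ Binomial(n, nir)
    p_gt_nir = float(stats.binom.sf(correct - 1, n, nir))

    sens = _ratio(cm.tp, truth_pos)
    spec = _ratio(cm.tn, truth_neg)
    ppv = _ratio(cm.tp, pred_pos)
    npv = _ratio(cm.tn, pred_neg)

    if min(truth_pos, truth_neg, pred_pos, pred_neg) > 0:
        p_e = (pred_pos * truth_pos + pred_neg * truth_neg) / (n * n)
        kappa = (accuracy - p_e) / (1.0 - p_e) if p_e < 1.0 else math.nan
    else:
        kappa = math.nan

    discordant = cm.fp + cm.fn
    if discordant == 0:
        mcnemar_stat, mcnemar_p = 0.0, 1.0
    else:
        mcnemar_stat = max(0.0, abs(cm.fp - cm.fn) - 1.0) ** 2 / discordant
        mcnemar_p = float(stats.chi2.sf(mcnemar_stat, df=1))

    return DiagnosticReport(
        accuracy=accuracy,
        accuracy_ci95=(float(ci.low), float(ci.high)),
        nir=nir,
        p_accuracy_gt_nir=p_gt_nir,
        kappa=kappa,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        detection_rate=_ratio(cm.tp, n),
        detection_prevalence=_ratio(pred_pos, n),
        balanced_accuracy=(sens + spec) / 2.0,
        mcnemar_statistic=float(mcnemar_stat),
        mcnemar_p=mcnemar_p,
    )


def evaluate_method(
    panels: Iterable[LipidPanel],
    method: LdlMethod,
    rule: DyslipidemiaRule = DyslipidemiaRule(),
) -> tuple[ConfusionMatrix, DiagnosticReport, int]:
    """Evaluate one calculated-LDL method against the direct reference standard.

    Truth labels come from (ldl_direct, tg, age); predictions apply the same
    rule to the calculated LDL (used even when flagged invalid, e.g. TG>400 —
    such panels are not excluded, mirroring screening practice).  Panels
    outside the rule's age window are excluded and counted.

    Returns (confusion matrix, diagnostic report, excluded subject count).
    """
    method = LdlMethod(method)
    if method is LdlMethod.DIRECT:
        raise ValueError("evaluating the direct method against itself is not an evaluation")
    calc = friedewald_ldl if method is LdlMethod.FRIEDEWALD else sampson_ldl

    preds: list[bool] = []
    truths: list[bool] = []
    excluded = 0
    for panel in panels:
        if panel.ldl_direct is None:
            raise ValueError(f"panel {panel.subject_id} lacks the direct LDL reference")
        try:
            truth = classify_dyslipidemia(panel.ldl_direct, panel.tg, panel.age_years, rule)
        except AgeOutOfRangeError:
            excluded += 1
            continue
        est = calc(panel.tc, panel.hdl, panel.tg)
        preds.append(classify_dyslipidemia(est.value, panel.tg, panel.age_years, rule))
        truths.append(truth)

    cm = confusion(preds, truths)
    return cm, diagnostic_metrics(cm), excluded
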