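"""Screening performance measures.

Sensitivity, specificity, accuracy, recall rate, false positive rate and AUC
for recall verdicts against the malignancy ground truth, with exact
Clopper-Pearson intervals, plus workload-reduction accounting. Reported
values are rounded half away from zero at 3 decimals (internal computation is
at full precision).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cohort import recall_truth
from .config import OperatingPoint
from .stats import clopper_pearson


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero; the message names the metric."""


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    A guard re-round at ``ndigits + 7`` places absorbs binary representation
    noise so that e.g. an exact half computed in floating point still rounds
    up.
    """
    d = Decimal(repr(round(float(x), ndigits + 7)))
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts with positive = image truly warrants recall."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerfSummary:
    """Point estimates with 95% Clopper-Pearson intervals.

    Workload fields are populated by :func:`summarize_strategy`; plain
    confusion-based summaries leave them ``None``.
    """

    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    accuracy: float
    accuracy_ci: tuple[float, float]
    recall_rate: float
    recall_rate_ci: tuple[float, float]
    false_positive_rate: float
    false_positive_rate_ci: tuple[float, float]
    auc: Optional[float] = None
    workload: Optional[int] = None
    workload_reduction: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(verdicts: np.ndarray, truths: np.ndarray) -> ConfusionTable:
    """Tally a confusion table from equal-length boolean vectors."""
    v = np.asarray(verdicts, dtype=bool)
    t = np.asarray(truths, dtype=bool)
    if v.shape != t.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {t.shape}")
    return ConfusionTable(
        tp=int((v & t).sum()),
        fp=int((v & ~t).sum()),
        tn=int((~v & ~t).sum()),
        fn=int((~v & t).sum()),
    )


def performance(conf: ConfusionTable, alpha: float = 0.05) -> PerfSummary:
    """All proportion metrics of a confusion table, each with its exact CI."""
    pos = conf.tp + conf.fn
    neg = conf.fp + conf.tn
    if pos == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive images")
    if neg == 0:
        raise UndefinedMetricError("specificity undefined: no negative images")
    n = conf.n
    return PerfSummary(
        sensitivity=conf.tp / pos,
        sensitivity_ci=clopper_pearson(conf.tp, pos, alpha),
        specificity=conf.tn / neg,
        specificity_ci=clopper_pearson(conf.tn, neg, alpha),
        accuracy=(conf.tp + conf.tn) / n,
        accuracy_ci=clopper_pearson(conf.tp + conf.tn, n, alpha),
        recall_rate=(conf.tp + conf.fp) / n,
        recall_rate_ci=clopper_pearson(conf.tp + conf.fp, n, alpha),
        false_positive_rate=conf.fp / neg,
        false_positive_rate_ci=clopper_pearson(conf.fp, neg, alpha),
    )


def single_point_auc(op: OperatingPoint) -> float:
    """Trapezoidal area of the ROC polyline (0,0) -> (1-spec, sens) -> (1,1).

    For a binary decision rule this equals (sensitivity + specificity) / 2
    and reproduces the ROC-plane placement of single operating points.
    """
    return (op.sensitivity + op.specificity) / 2.0


def empirical_roc_auc(scores: np.ndarray, truths: np.ndarray) -> float:
    """Trapezoidal AUC over all score thresholds (ties by rank-midpoint)."""
    t = np.asarray(truths, dtype=bool)
    if t.all() or not t.any():
        raise UndefinedMetricError("AUC undefined: only one class present")
    return float(roc_auc_score(t, np.asarray(scores, dtype=float)))


def workload_reduction(w_strategy: int, w_reference: int) -> float:
    """Fractional reduction relative to the reference workload.

    Negative when the strategy reads more than the reference.
    """
    if w_reference <= 0:
        raise ValueError("reference workload must be positive")
    return (w_reference - w_strategy) / w_reference


def summarize_strategy(
    cohort: pd.DataFrame,
    decisions: pd.DataFrame,
    reference_workload: Optional[int] = None,
    alpha: float = 0.05,
) -> PerfSummary:
    """Full per-strategy summary: confusion metrics, AUC, workload."""
    from .strategies import count_workload, recall_labels

    verdict, truth = recall_labels(decisions, cohort)
    conf = confusion(verdict, truth)
    summary = performance(conf, alpha=alpha)
    summary.auc = single_point_auc(
        OperatingPoint(
            sensitivity=summary.sensitivity, specificity=summary.specificity
        )
    )
    summary.workload = count_workload(decisions)["total"]
    if reference_workload is not None:
        summary.workload_reduction = workload_reduction(
            summary.workload, reference_workload
        )
    return summary


def subgroup_performance(
    cohort: pd.DataFrame,
    decisions: pd.DataFrame,
    include_no_lesion: bool = False,
    alpha: float = 0.05,
) -> dict[str, PerfSummary]:
    """Per-size-class performance on lesion-bearing images.

    Subgroups are defined by lesion size, so by default only lesion images
    enter and benign lesions serve as the negatives; set
    ``include_no_lesion`` to add no-lesion images to every subgroup's
    negative pool instead.
    """
    verdict = (
        decisions.set_index("image_id")["recall"]
        .reindex(cohort["image_id"])
        .to_numpy(dtype=bool)
    )
    truth = recall_truth(cohort)
    lesion = cohort["has_lesion"].to_numpy(dtype=bool)
    size = cohort["size_class"].fillna("").to_numpy(dtype=object)

    groups = sorted({s for s, l in zip(size, lesion) if l and s})
    if not groups:
        raise UndefinedMetricError("no lesion images: subgroups are empty")
    out: dict[str, PerfSummary] = {}
    for grp in groups:
        mask = lesion & (size == grp)
        if include_no_lesion:
            mask = mask | ~lesion
        out[grp] = performance(confusion(verdict[mask], truth[mask]), alpha=alpha)
    return out
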