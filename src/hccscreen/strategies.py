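"""The five screening decision workflows.

Every workflow turns one cohort row into a recall / no-recall verdict while
accounting for the radiologist reads it consumes at the detection and the
classification stage:

* ``original`` — the guideline pathway: a radiologist reads every image and
  decides recall directly (one read per image).
* ``s1`` — stand-alone AI: the detector flags lesions, the classifier score
  thresholded at the cutoff decides recall; no radiologist reads.
* ``s2`` — AI triage at detection: detector-negative images get a radiologist
  detection review; images deemed lesion-bearing (by AI or reviewer) are
  decided by the classifier score.
* ``s3`` — AI triage plus AI-assisted reading: detection as in ``s2``; every
  lesion-bearing image is then read by the AI-assisted radiologist.
* ``s4`` — AI triage with a safety net at both stages: detection as in
  ``s2``; classifier-recalls stand, classifier-benign images get a
  radiologist classification review that makes the final call.

Images the detection review also deems lesion-free exit as no-recall without
any classification read. Workload is counted in image-reads per stage, so an
image read at both stages contributes two reads (which is how ``s3`` can
exceed the cohort size).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import recall_truth
from .config import STRATEGY_IDS

DECISION_COLUMNS = [
    "image_id",
    "strategy_id",
    "recall",
    "detection_reads",
    "classification_reads",
    "recall_prob",
    "deciding_agent",
]

_REQUIRED: dict[str, tuple[str, ...]] = {
    "original": ("rad_class_flag", "rad_confidence"),
    "s1": ("detector_flag", "classifier_score"),
    "s2": ("detector_flag", "rad_detect_flag", "classifier_score", "rad_confidence"),
    "s3": (
        "detector_flag",
        "rad_detect_flag",
        "rad_assisted_flag",
        "rad_confidence",
    ),
    "s4": (
        "detector_flag",
        "rad_detect_flag",
        "classifier_score",
        "rad_class_flag",
        "rad_confidence",
    ),
}


class StrategyError(ValueError):
    """Unknown strategy or decisions from mixed strategies."""


class SchemaError(ValueError):
    """Cohort table lacks a column required by the requested strategy."""


class JoinError(ValueError):
    """Decision and cohort tables do not cover the same image ids."""


def apply_strategy(
    cohort: pd.DataFrame, strategy_id: str, cutoff: float = 0.2
) -> pd.DataFrame:
    """Evaluate one workflow on a cohort, one decision row per image.

    Parameters
    ----------
    cohort : DataFrame
        Cohort table with the agent-output columns the strategy needs.
    strategy_id : str
        One of ``original, s1, s2, s3, s4``.
    cutoff : float
        Classifier score threshold; a score at or above the cutoff counts as
        a malignancy call (ties favour recall).
    """
    if strategy_id not in STRATEGY_IDS:
        raise StrategyError(
            f"unknown strategy {strategy_id!r}; expected one of {STRATEGY_IDS}"
        )
    for col in _REQUIRED[strategy_id]:
        if col not in cohort.columns:
            raise SchemaError(f"strategy {strategy_id!r} requires column {col!r}")

    n = len(cohort)
    recall = np.zeros(n, dtype=bool)
    det_reads = np.zeros(n, dtype=np.int64)
    cls_reads = np.zeros(n, dtype=np.int64)
    prob = np.zeros(n, dtype=float)
    agent = np.full(n, "ai", dtype=object)

    if strategy_id == "original":
        recall = cohort["rad_class_flag"].to_numpy(dtype=bool)
        cls_reads[:] = 1
        prob = cohort["rad_confidence"].to_numpy(dtype=float)
        agent[:] = "radiologist"
    elif strategy_id == "s1":
        det = cohort["detector_flag"].to_numpy(dtype=bool)
        score = cohort["classifier_score"].to_numpy(dtype=float)
        recall = det & (score >= cutoff)
        prob = np.where(det, score, 0.0)
    else:
        det = cohort["detector_flag"].to_numpy(dtype=bool)
        reviewed = ~det
        rad_det = cohort["rad_detect_flag"].to_numpy(dtype=bool)
        lesion_bearing = det | (reviewed & rad_det)
        det_reads[reviewed] = 1
        conf = cohort["rad_confidence"].to_numpy(dtype=float)

        # detection-review exits: radiologist-certified no-recall
        exit_mask = reviewed & ~rad_det
        prob[exit_mask] = conf[exit_mask]
        agent[exit_mask] = "radiologist"

        lb = lesion_bearing
        if strategy_id == "s2":
            score = cohort["classifier_score"].to_numpy(dtype=float)
            recall[lb] = score[lb] >= cutoff
            prob[lb] = score[lb]
            agent[lb] = "ai"
        elif strategy_id == "s3":
            assisted = cohort["rad_assisted_flag"].to_numpy(dtype=bool)
            cls_reads[lb] = 1
            recall[lb] = assisted[lb]
            prob[lb] = conf[lb]
            agent[lb] = "radiologist_assisted"
        else:  # s4
            score = cohort["classifier_score"].to_numpy(dtype=float)
            ai_recall = lb & (score >= cutoff)
            recall[ai_recall] = True
            prob[ai_recall] = score[ai_recall]
            agent[ai_recall] = "ai"
            review = lb & ~ai_recall
            cls_reads[review] = 1
            rad_cls = cohort["rad_class_flag"].to_numpy(dtype=bool)
            recall[review] = rad_cls[review]
            prob[review] = conf[review]
            agent[review] = "radiologist"

    return pd.DataFrame(
        {
            "image_id": cohort["image_id"].to_numpy(),
            "strategy_id": strategy_id,
            "recall": recall,
            "detection_reads": det_reads,
            "classification_reads": cls_reads,
            "recall_prob": prob,
            "deciding_agent": agent,
        },
        columns=DECISION_COLUMNS,
    )


def count_workload(decisions: pd.DataFrame) -> dict[str, int]:
    """Total radiologist image-reads consumed by one strategy's decisions.

    Returns ``{"total", "detection_reads", "classification_reads"}``; an
    image read at both stages counts twice.
    """
    sids = decisions["strategy_id"].unique()
    if len(sids) != 1:
        raise StrategyError(f"decisions mix strategies: {sorted(sids)}")
    d = int(decisions["detection_reads"].sum())
    c = int(decisions["classification_reads"].sum())
    return {"total": d + c, "detection_reads": d, "classification_reads": c}


def recall_labels(
    decisions: pd.DataFrame, cohort: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Join verdicts with ground truth, aligned on image_id (cohort order)."""
    miss_c = set(decisions["image_id"]) - set(cohort["image_id"])
    miss_d = set(cohort["image_id"]) - set(decisions["image_id"])
    if miss_c or miss_d:
        raise JoinError(
            f"unmatched image ids; only in decisions: {sorted(miss_c)[:5]}, "
            f"only in cohort: {sorted(miss_d)[:5]}"
        )
    verdict = (
        decisions.set_index("image_id")["recall"]
        .reindex(cohort["image_id"])
        .to_numpy(dtype=bool)
    )
    return verdict, recall_truth(cohort)
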