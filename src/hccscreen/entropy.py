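"""Shannon-entropy uncertainty analysis of strategy decisions.

Each decision carries the probability of recall assigned by its final
decider (classifier score for AI decisions, the radiologist's reported
confidence otherwise). The binary Shannon entropy of that probability,

    H(p) = -p log2 p - (1 - p) log2 (1 - p)   [bits],

quantifies how uncertain the decision was: 0 for a certain call, 1 for a
coin flip. The profile summarises entropies per strategy overall and on the
incorrect decisions, and reports the error rate inside the low-entropy
("high certainty") subset H < threshold, default threshold 0.1 bits.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import xlogy


@dataclass
class EntropySummary:
    """Per-strategy entropy profile (all bits; IQR = Q3 - Q1 width)."""

    strategy_id: str
    n_decisions: int
    median_entropy: float
    iqr_entropy: float
    n_errors: int
    median_entropy_errors: Optional[float]
    iqr_entropy_errors: Optional[float]
    low_entropy_threshold: float
    n_low_entropy: int
    n_low_entropy_errors: int
    low_entropy_error_rate: Optional[float]

    def to_dict(self) -> dict:
        return asdict(self)


def shannon_entropy(p_recall) -> np.ndarray | float:
    """Binary Shannon entropy in bits, with 0*log2(0) = 0."""
    p = np.asarray(p_recall, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("recall probability must lie in [0, 1]")
    h = -(xlogy(p, p) + xlogy(1 - p, 1 - p)) / np.log(2)
    return float(h) if np.isscalar(p_recall) else h


def entropy_profile(
    decisions: pd.DataFrame, truths: np.ndarray, threshold: float = 0.1
) -> EntropySummary:
    """Summarise decision entropies of one strategy.

    ``truths`` must align row-for-row with ``decisions``; an error is a
    verdict differing from the ground truth. Error-subset summaries are
    ``None`` when there are no errors, and the low-entropy error rate is
    ``None`` when the low-entropy subset is empty.
    """
    if len(decisions) == 0:
        raise ValueError("empty decision set")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sids = decisions["strategy_id"].unique()
    if len(sids) != 1:
        raise ValueError(f"decisions mix strategies: {sorted(sids)}")

    truths = np.asarray(truths, dtype=bool)
    recall = decisions["recall"].to_numpy(dtype=bool)
    if truths.shape != recall.shape:
        raise ValueError("truths must align with decisions")

    h = shannon_entropy(decisions["recall_prob"].to_numpy(dtype=float))
    err = recall != truths
    low = h < threshold

    def q(x: np.ndarray) -> tuple[float, float]:
        return float(np.median(x)), float(
            np.percentile(x, 75) - np.percentile(x, 25)
        )

    med, iqr = q(h)
    med_e, iqr_e = q(h[err]) if err.any() else (None, None)
    n_low = int(low.sum())
    n_low_err = int((low & err).sum())
    return EntropySummary(
        strategy_id=str(sids[0]),
        n_decisions=len(decisions),
        median_entropy=med,
        iqr_entropy=iqr,
        n_errors=int(err.sum()),
        median_entropy_errors=med_e,
        iqr_entropy_errors=iqr_e,
        low_entropy_threshold=threshold,
        n_low_entropy=n_low,
        n_low_entropy_errors=n_low_err,
        low_entropy_error_rate=(n_low_err / n_low) if n_low else None,
    )


def calibration_fixture(
    n_low: int = 6052,
    n_low_errors: int = 482,
    n_high: int = 1000,
    p_low: float = 0.99,
    strategy_id: str = "s4",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic decision set with exact low-entropy counts.

    Builds ``n_low`` high-certainty decisions (recall probability ``p_low``,
    entropy ~0.08 bits) of which exactly ``n_low_errors`` are wrong, padded
    with ``n_high`` maximally uncertain decisions (p = 0.5). Defaults encode
    the published Strategy 4 low-entropy profile: 482 errors among 6052
    sub-threshold decisions. Returns (decisions, truths).
    """
    if n_low_errors > n_low:
        raise ValueError("n_low_errors cannot exceed n_low")
    if shannon_entropy(p_low) >= 0.1:
        raise ValueError("p_low must give entropy below 0.1 bits")
    n = n_low + n_high
    recall = np.ones(n, dtype=bool)
    prob = np.concatenate([np.full(n_low, p_low), np.full(n_high, 0.5)])
    truths = recall.copy()
    truths[:n_low_errors] = False  # the engineered low-entropy errors
    decisions = pd.DataFrame(
        {
            "image_id": [f"img{i:06d}" for i in range(n)],
            "strategy_id": strategy_id,
            "recall": recall,
            "detection_reads": 0,
            "classification_reads": 0,
            "recall_prob": prob,
            "deciding_agent": "ai",
        }
    )
    return decisions, truths
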