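"""Independent brute-force oracles used by the tests.

Deliberately naive implementations (case-by-case branching, pair counting,
tail-probability root finding) kept separate from the library code paths
they check.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def strategy_oracle_row(row: dict, strategy_id: str, cutoff: float) -> dict:
    """Walk one image through one workflow flowchart, case by case."""
    det = bool(row["detector_flag"])
    score = float(row["classifier_score"])
    rad_det = bool(row["rad_detect_flag"])
    rad_cls = bool(row["rad_class_flag"])
    rad_ast = bool(row["rad_assisted_flag"])
    conf = float(row["rad_confidence"])

    if strategy_id == "original":
        return dict(recall=rad_cls, det_reads=0, cls_reads=1,
                    prob=conf, agent="radiologist")

    if strategy_id == "s1":
        if det:
            if score >= cutoff:
                return dict(recall=True, det_reads=0, cls_reads=0,
                            prob=score, agent="ai")
            return dict(recall=False, det_reads=0, cls_reads=0,
                        prob=score, agent="ai")
        return dict(recall=False, det_reads=0, cls_reads=0, prob=0.0, agent="ai")

    # shared triage stage of s2/s3/s4
    if det:
        lesion_bearing, det_reads = True, 0
    else:
        det_reads = 1
        if rad_det:
            lesion_bearing = True
        else:
            return dict(recall=False, det_reads=det_reads, cls_reads=0,
                        prob=conf, agent="radiologist")

    if strategy_id == "s2":
        return dict(recall=score >= cutoff, det_reads=det_reads, cls_reads=0,
                    prob=score, agent="ai")
    if strategy_id == "s3":
        return dict(recall=rad_ast, det_reads=det_reads, cls_reads=1,
                    prob=conf, agent="radiologist_assisted")
    if strategy_id == "s4":
        if score >= cutoff:
            return dict(recall=True, det_reads=det_reads, cls_reads=0,
                        prob=score, agent="ai")
        return dict(recall=rad_cls, det_reads=det_reads, cls_reads=1,
                    prob=conf, agent="radiologist")
    raise ValueError(strategy_id)


def pairwise_auc(scores, truths) -> float:
    """AUC as the fraction of concordant positive-negative pairs (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    pos = scores[truths]
    neg = scores[~truths]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def clopper_pearson_by_inversion(k: int, n: int, alpha: float) -> tuple[float, float]:
    """Exact interval by root-finding on the binomial tail probabilities."""
    if k == 0:
        lo = 0.0
    else:
        lo = optimize.brentq(
            lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12
        )
    if k == n:
        hi = 1.0
    else:
        hi = optimize.brentq(
            lambda p: stats.binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12
        )
    return lo, hi


def binomial_interval(n: int, p: float, conf: float) -> tuple[int, int]:
    """Central interval of realized successes for Binomial(n, p)."""
    a = (1 - conf) / 2
    return int(stats.binom.ppf(a, n, p)), int(stats.binom.isf(a, n, p))
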