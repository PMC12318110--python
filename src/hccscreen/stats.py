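"""Interval estimation, margin-based conclusions and hypothesis tests.

The conventions follow the screening-evaluation playbook: exact
Clopper-Pearson 95% intervals for proportions; a 5% *relative*
noninferiority margin on sensitivity and a 1% *absolute* superiority margin
on specificity, both judged on the lower limit of the rate-difference CI;
two-sided z / chi-square / Mann-Whitney tests; the DeLong method for paired
AUC comparisons; and a Bonferroni-adjusted alpha of 0.05/n.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import (
    confint_proportions_2indep,
    proportion_confint,
    proportions_ztest,
)

Conclusion = str  # "noninferior" | "superior" | "not_shown"


@dataclass
class ComparisonResult:
    """One (strategy vs reference, metric) margin comparison."""

    metric: str
    estimate_new: float
    estimate_ref: float
    rate_difference: float
    diff_ci: tuple[float, float]
    p_value: float
    margin: float
    conclusion: Conclusion
    alpha_adjusted: float

    def to_dict(self) -> dict:
        return asdict(self)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (beta-quantile) confidence interval for k/n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"require 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    # statsmodels returns NaN at the boundary cases; pin them
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return lo, hi


def rate_difference_ci(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    alpha: float = 0.05,
    method: str = "wald",
) -> tuple[float, float, float]:
    """Difference of proportions k1/n1 - k2/n2 with its CI.

    ``method`` is ``"wald"`` (default) or ``"newcomb"`` (score-based
    Newcombe interval); both delegate to statsmodels.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    diff = k1 / n1 - k2 / n2
    lo, hi = confint_proportions_2indep(
        k1, n1, k2, n2, method=method, compare="diff", alpha=alpha
    )
    return diff, float(lo), float(hi)


def noninferiority(
    sens_new: float,
    sens_ref: float,
    diff_ci: tuple[float, float],
    relative_margin: float = 0.05,
) -> Conclusion:
    """Relative-margin noninferiority call on a sensitivity difference.

    The absolute margin is ``relative_margin * sens_ref``; noninferiority is
    shown iff the lower CI limit of (new - ref) strictly exceeds its
    negative.
    """
    if not 0 < relative_margin < 1:
        raise ValueError("relative_margin must lie in (0, 1)")
    margin_abs = relative_margin * sens_ref
    return "noninferior" if diff_ci[0] > -margin_abs else "not_shown"


def superiority(
    spec_new: float,
    spec_ref: float,
    diff_ci: tuple[float, float],
    absolute_margin: float = 0.01,
) -> Conclusion:
    """Absolute-margin superiority call on a specificity difference."""
    del spec_new, spec_ref  # margin is absolute; estimates kept for symmetry
    return "superior" if diff_ci[0] > absolute_margin else "not_shown"


def proportion_z_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-proportion z-test p-value."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if k1 == k2 and n1 == n2 and (k1 in (0, n1)):
        return 1.0  # degenerate: identical boundary proportions
    _, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(p)


def chi_square_accuracy(conf_a, conf_b) -> float:
    """Chi-square test on correct-vs-incorrect counts of two strategies."""
    table = np.array(
        [
            [conf_a.tp + conf_a.tn, conf_a.fp + conf_a.fn],
            [conf_b.tp + conf_b.tn, conf_b.fp + conf_b.fn],
        ]
    )
    if table.sum(axis=1).min() == 0:
        raise ValueError("degenerate confusion tables")
    return float(sps.chi2_contingency(table, correction=False).pvalue)


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney U test p-value (normal approx with ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def bonferroni(alpha: float, n_comparisons: int) -> float:
    """Adjusted per-comparison alpha = alpha / n."""
    if n_comparisons <= 0:
        raise ValueError("n_comparisons must be positive")
    return alpha / n_comparisons


# ---------------------------------------------------------------------------
# DeLong test for paired AUCs
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, truths: np.ndarray):
    """Structural components (V10, V01) and the AUC of one score vector."""
    pos = scores[truths]
    neg = scores[~truths]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n          # per-positive placement values
    v01 = 1.0 - (all_r[m:] - neg_r) / m    # per-negative placement values
    return auc, v10, v01


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    variance: float
    p_value: float


def delong_auc_test(scores_a, scores_b, truths) -> DelongResult:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both score vectors must be evaluated on the same images. For rule-based
    strategies, pass the per-image recall probability as the score.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    t = np.asarray(truths, dtype=bool)
    if a.shape != t.shape or b.shape != t.shape:
        raise ValueError("scores and truths must have equal length")
    if t.all() or not t.any():
        raise ValueError("both classes must be present")

    auc_a, v10_a, v01_a = _delong_components(a, t)
    auc_b, v10_b, v01_b = _delong_components(b, t)
    m, n = v10_a.size, v01_a.size

    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]

    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return DelongResult(auc_a=float(auc_a), auc_b=float(auc_b),
                        variance=float(max(var, 0.0)), p_value=p)


def delong_auc_variance(scores, truths) -> tuple[float, float]:
    """Single-AUC DeLong variance (the one-classifier reduction)."""
    t = np.asarray(truths, dtype=bool)
    auc, v10, v01 = _delong_components(np.asarray(scores, dtype=float), t)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    return float(auc), float(var)


def compare_rates(
    metric: str,
    k_new: int,
    n_new: int,
    k_ref: int,
    n_ref: int,
    margin: float,
    margin_kind: str,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    ci_method: str = "wald",
) -> ComparisonResult:
    """Full margin comparison of one proportion metric vs the reference.

    ``margin_kind`` is ``"relative_noninferiority"`` (sensitivity convention)
    or ``"absolute_superiority"`` (specificity convention).
    """
    est_new, est_ref = k_new / n_new, k_ref / n_ref
    diff, lo, hi = rate_difference_ci(
        k_new, n_new, k_ref, n_ref, alpha=alpha, method=ci_method
    )
    p = proportion_z_test(k_new, n_new, k_ref, n_ref)
    if margin_kind == "relative_noninferiority":
        concl = noninferiority(est_new, est_ref, (lo, hi), margin)
    elif margin_kind == "absolute_superiority":
        concl = superiority(est_new, est_ref, (lo, hi), margin)
    else:
        raise ValueError(f"unknown margin_kind {margin_kind!r}")
    return ComparisonResult(
        metric=metric,
        estimate_new=est_new,
        estimate_ref=est_ref,
        rate_difference=diff,
        diff_ci=(lo, hi),
        p_value=p,
        margin=margin,
        conclusion=concl,
        alpha_adjusted=bonferroni(alpha, n_comparisons),
    )
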