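"""End-to-end orchestration: cohort -> decisions -> reports.

Used by the command-line interface; each stage logs one structured line
(stage, rows, elapsed seconds, seed).
"""

from __future__ import annotations

import logging
import time
from typing import Optional

import pandas as pd

from . import metrics, stats
from .cohort import generate_cohort, paper_fixture
from .config import RunConfig
from .entropy import entropy_profile
from .strategies import apply_strategy, count_workload, recall_labels

log = logging.getLogger("hccscreen")

_KNOWN_FIXTURES = {"paper_fixture": paper_fixture}


def _stage(name: str, n_rows: int, t0: float, seed) -> None:
    log.info(
        "stage=%s rows=%d elapsed=%.3fs seed=%s", name, n_rows, time.time() - t0, seed
    )


def build_cohort(config: RunConfig) -> pd.DataFrame:
    t0 = time.time()
    if config.mode == "fixture":
        if config.fixture_name not in _KNOWN_FIXTURES:
            raise ValueError(f"unknown fixture {config.fixture_name!r}")
        cohort = _KNOWN_FIXTURES[config.fixture_name]()
        seed = None
    else:
        cohort_cfg = config.cohort
        if config.seed is not None:
            cohort_cfg = cohort_cfg.model_copy(update={"seed": config.seed})
        cohort = generate_cohort(cohort_cfg)
        seed = cohort_cfg.seed
    _stage("cohort", len(cohort), t0, seed)
    return cohort


def run_strategies(config: RunConfig, cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    t0 = time.time()
    decisions = {
        sid: apply_strategy(cohort, sid, cutoff=config.cutoff)
        for sid in config.strategies
    }
    _stage("strategies", sum(len(d) for d in decisions.values()), t0, config.seed)
    return decisions


def performance_report(
    config: RunConfig,
    cohort: pd.DataFrame,
    decisions: dict[str, pd.DataFrame],
) -> dict:
    """Per-strategy metrics, workloads and confusion counts (table shape)."""
    t0 = time.time()
    ref_workload: Optional[int] = None
    if "original" in decisions:
        ref_workload = count_workload(decisions["original"])["total"]
    out: dict = {"reference": "original", "alpha": config.alpha, "strategies": {}}
    for sid, dec in decisions.items():
        verdict, truth = recall_labels(dec, cohort)
        conf = metrics.confusion(verdict, truth)
        summary = metrics.summarize_strategy(
            cohort, dec, reference_workload=ref_workload, alpha=config.alpha
        )
        entry = summary.to_dict()
        entry["confusion"] = {
            "tp": conf.tp, "fp": conf.fp, "tn": conf.tn, "fn": conf.fn
        }
        entry["workload_detail"] = count_workload(dec)
        out["strategies"][sid] = entry
    _stage("performance", len(out["strategies"]), t0, config.seed)
    return out


def comparison_report(config: RunConfig, perf: dict) -> dict:
    """Margin comparisons of every non-reference strategy vs the reference."""
    t0 = time.time()
    ref_id = perf["reference"]
    strategies = perf["strategies"]
    if ref_id not in strategies:
        return {"reference": ref_id, "comparisons": []}
    ref = strategies[ref_id]["confusion"]
    others = [s for s in strategies if s != ref_id]
    n_comp = config.bonferroni_n or max(len(others), 1)
    comps = []
    for sid in others:
        c = strategies[sid]["confusion"]
        sens = stats.compare_rates(
            "sensitivity",
            c["tp"], c["tp"] + c["fn"],
            ref["tp"], ref["tp"] + ref["fn"],
            margin=config.relative_sensitivity_margin,
            margin_kind="relative_noninferiority",
            alpha=config.alpha,
            n_comparisons=n_comp,
        )
        spec = stats.compare_rates(
            "specificity",
            c["tn"], c["tn"] + c["fp"],
            ref["tn"], ref["tn"] + ref["fp"],
            margin=config.absolute_specificity_margin,
            margin_kind="absolute_superiority",
            alpha=config.alpha,
            n_comparisons=n_comp,
        )
        conf_s = metrics.ConfusionTable(**c)
        conf_r = metrics.ConfusionTable(**ref)
        acc_p = stats.chi_square_accuracy(conf_s, conf_r)
        wl_p = stats.proportion_z_test(
            strategies[sid]["workload"], conf_s.n * 2,
            strategies[ref_id]["workload"], conf_r.n * 2,
        )
        comps.append(
            {
                "strategy": sid,
                "reference": ref_id,
                "sensitivity": sens.to_dict(),
                "specificity": spec.to_dict(),
                "accuracy_p_value": acc_p,
                "workload_p_value": wl_p,
                "bonferroni_n": n_comp,
            }
        )
    _stage("comparisons", len(comps), t0, config.seed)
    return {"reference": ref_id, "comparisons": comps}


def entropy_report(
    config: RunConfig,
    cohort: pd.DataFrame,
    decisions: dict[str, pd.DataFrame],
) -> dict:
    """Entropy profile per strategy plus pairwise distribution tests."""
    t0 = time.time()
    from .entropy import shannon_entropy

    profiles = {}
    vectors = {}
    for sid, dec in decisions.items():
        _, truth = recall_labels(dec, cohort)
        profiles[sid] = entropy_profile(
            dec, truth, threshold=config.entropy_threshold
        ).to_dict()
        vectors[sid] = shannon_entropy(dec["recall_prob"].to_numpy(dtype=float))
    pair_p = {}
    sids = list(decisions)
    for i, a in enumerate(sids):
        for b in sids[i + 1 :]:
            pair_p[f"{a}_vs_{b}"] = stats.mann_whitney(vectors[a], vectors[b])
    n_pairs = max(len(pair_p), 1)
    out = {
        "profiles": profiles,
        "pairwise_mann_whitney_p": pair_p,
        "alpha_adjusted": stats.bonferroni(config.alpha, n_pairs),
    }
    _stage("entropy", len(profiles), t0, config.seed)
    return out
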