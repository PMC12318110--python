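"""Synthetic screening cohorts: stochastic generation and exact-count fixtures.

A cohort is a pandas DataFrame with one row per screening image, carrying the
ground truth (lesion presence, malignancy, size class) together with the
simulated outputs of every decision agent involved in the workflows: the AI
lesion detector, the AI malignancy classifier (a score in [0, 1], thresholded
at a cutoff), and the radiologist's unassisted, detection-review and
AI-assisted calls plus a recall probability for the uncertainty analysis.

Two construction modes are provided:

* :func:`generate_cohort` — seeded stochastic sampling from a
  :class:`~hccscreen.config.CohortConfig`; each agent's empirical operating
  point converges to its configured value.
* :func:`build_fixture` / :func:`paper_fixture` — deterministic tables whose
  confusion cells match integer specifications exactly, used to reproduce the
  published aggregate counts (e.g. 165 detector false negatives, 180 false
  positives, 3676/4021 correct detections).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import ValidationError
from scipy import optimize, stats

from .config import CLASSES, CohortConfig, ConfidenceModel, OperatingPoint

#: Exact column order of a serialized cohort table.
COHORT_COLUMNS = [
    "image_id",
    "screening_id",
    "center_id",
    "has_lesion",
    "malignant",
    "size_class",
    "detector_flag",
    "classifier_score",
    "rad_detect_flag",
    "rad_class_flag",
    "rad_assisted_flag",
    "rad_confidence",
]

SIZE_CLASSES = ("lt1cm", "ge1cm")


class CohortConfigError(ValueError):
    """Invalid cohort configuration (offending field named in the message)."""


class FixtureError(ValueError):
    """Inconsistent exact-count fixture specification."""


def recall_truth(cohort: pd.DataFrame) -> np.ndarray:
    """Ground-truth recall label: image contains a malignant lesion."""
    mal = cohort["malignant"].fillna(False).to_numpy(dtype=bool)
    return cohort["has_lesion"].to_numpy(dtype=bool) & mal


# ---------------------------------------------------------------------------
# stochastic generation
# ---------------------------------------------------------------------------


def _solve_beta_b(shape: float, cutoff: float, target_cdf: float) -> float:
    """Second Beta shape parameter b with Beta(shape, b).cdf(cutoff) = target.

    The CDF at a fixed point is strictly increasing in b, so a bracketed
    root-find on log(b) suffices.
    """

    def f(log_b: float) -> float:
        return stats.beta.cdf(cutoff, shape, np.exp(log_b)) - target_cdf

    lo, hi = -12.0, 12.0
    if f(lo) > 0 or f(hi) < 0:  # target outside achievable range for this shape
        raise ValueError("target CDF unreachable for the given shape")
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-12)))


def _sample_scores(
    rng: np.random.Generator,
    n: int,
    shape: float,
    cutoff: float,
    target_cdf: float,
) -> np.ndarray:
    """Draw classifier scores with P(score < cutoff) = target_cdf exactly.

    Degenerate targets (0 or 1) put all mass on one side of the cutoff using
    a scaled Beta(shape, shape) law.
    """
    if n == 0:
        return np.empty(0)
    if target_cdf <= 1e-12:
        return cutoff + (1.0 - cutoff) * rng.beta(shape, shape, size=n)
    if target_cdf >= 1.0 - 1e-12:
        return cutoff * rng.beta(shape, shape, size=n)
    b = _solve_beta_b(shape, cutoff, target_cdf)
    return rng.beta(shape, b, size=n)


def _screening_ids(rng: np.random.Generator, n: int, mean_per_screening: float) -> np.ndarray:
    """Group consecutive images into screenings of size 1 or 2.

    A fraction p = mean - 1 of screenings carry two images, giving the
    configured mean images-per-screening.
    """
    p_two = float(np.clip(mean_per_screening - 1.0, 0.0, 1.0))
    ids = np.empty(n, dtype=np.int64)
    sid, i = 0, 0
    while i < n:
        size = 2 if (rng.random() < p_two and i + 1 < n) else 1
        ids[i : i + size] = sid
        sid += 1
        i += size
    return ids


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Sample a seeded synthetic cohort table.

    Identical config (including seed) yields an identical table. Each agent's
    empirical sensitivity/specificity is binomially distributed around its
    configured operating point.

    Raises
    ------
    CohortConfigError
        If the configuration violates a constraint; the message names the
        offending field.
    """
    if not isinstance(config, CohortConfig):
        try:
            config = CohortConfig.model_validate(config)
        except ValidationError as exc:  # re-raise with domain error type
            raise CohortConfigError(str(exc)) from exc

    rng = np.random.default_rng(config.seed)
    n = config.n_images

    cls = rng.choice(
        3, size=n, p=[config.frac_malignant, config.frac_benign, config.frac_no_lesion]
    )
    has_lesion = cls < 2
    malignant_raw = cls == 0
    truth = has_lesion & malignant_raw

    size_lt1 = rng.random(n) < config.size_fraction_lt1cm

    def bern(p: float, size: int) -> np.ndarray:
        return rng.random(size) < p

    det = config.detector
    detector_flag = np.where(
        has_lesion, bern(det.sensitivity, n), bern(1.0 - det.specificity, n)
    )

    clf = config.classifier
    scores = np.empty(n)
    pos = truth
    scores[pos] = _sample_scores(
        rng, int(pos.sum()), config.score_shape, config.cutoff, 1.0 - clf.sensitivity
    )
    scores[~pos] = _sample_scores(
        rng, int((~pos).sum()), config.score_shape, config.cutoff, clf.specificity
    )

    ro = config.radiologist_original
    rad_class = np.where(truth, bern(ro.sensitivity, n), bern(1.0 - ro.specificity, n))

    rd = config.radiologist_detect_review
    rad_detect = np.where(
        has_lesion, bern(rd.sensitivity, n), bern(1.0 - rd.specificity, n)
    )

    ra = config.radiologist_assisted
    rad_assist = np.where(truth, bern(ra.sensitivity, n), bern(1.0 - ra.specificity, n))

    conf = _confidence(config.confidence, rad_class.astype(bool), truth)

    df = pd.DataFrame(
        {
            "image_id": [f"img{i:06d}" for i in range(n)],
            "screening_id": [
                f"scr{s:06d}"
                for s in _screening_ids(rng, n, config.images_per_screening)
            ],
            "center_id": rng.integers(1, config.n_centers + 1, size=n),
            "has_lesion": has_lesion,
            "malignant": pd.array(
                np.where(has_lesion, malignant_raw, None), dtype="boolean"
            ),
            "size_class": pd.array(
                np.where(
                    has_lesion, np.where(size_lt1, "lt1cm", "ge1cm"), None
                ),
                dtype="string",
            ),
            "detector_flag": detector_flag.astype(bool),
            "classifier_score": scores,
            "rad_detect_flag": rad_detect.astype(bool),
            "rad_class_flag": rad_class.astype(bool),
            "rad_assisted_flag": rad_assist.astype(bool),
            "rad_confidence": conf,
        },
        columns=COHORT_COLUMNS,
    )
    return df


def _confidence(
    model: ConfidenceModel, call_recall: np.ndarray, truth: np.ndarray
) -> np.ndarray:
    correct = call_recall == truth
    c = np.where(correct, model.concordant, model.discordant)
    return np.where(call_recall, c, 1.0 - c)


# ---------------------------------------------------------------------------
# exact-count fixtures
# ---------------------------------------------------------------------------


def _apportion(total: int, sizes: np.ndarray) -> np.ndarray:
    """Split ``total`` across strata proportionally to ``sizes``.

    Largest-remainder (Hamilton) rounding; deterministic, ties broken by
    stratum order. Each share is capped at its stratum size.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    if total < 0 or total > sizes.sum():
        raise FixtureError(
            f"count {total} cannot be apportioned into strata of sizes {sizes.tolist()}"
        )
    if sizes.sum() == 0:
        return np.zeros_like(sizes)
    quota = total * sizes / sizes.sum()
    out = np.floor(quota).astype(np.int64)
    remainder = quota - out
    # distribute leftovers to largest remainders, respecting capacities
    order = np.argsort(-remainder, kind="stable")
    left = total - out.sum()
    for idx in order:
        if left == 0:
            break
        if out[idx] < sizes[idx]:
            out[idx] += 1
            left -= 1
    # overflow repair (possible when a stratum was saturated)
    for idx in np.argsort(remainder, kind="stable"):
        if left == 0:
            break
        room = sizes[idx] - out[idx]
        add = min(room, left)
        out[idx] += add
        left -= add
    return out


@dataclass(frozen=True)
class ClassCounts:
    """Exact per-class cell counts for one image class of a fixture."""

    n: int
    detector_negatives: int
    classifier_positives: int
    rad_class_positives: int
    rad_detect_positives: int
    rad_assisted_positives: int
    lt1cm: int = 0

    def validate(self, name: str) -> None:
        for fname in (
            "detector_negatives",
            "classifier_positives",
            "rad_class_positives",
            "rad_detect_positives",
            "rad_assisted_positives",
            "lt1cm",
        ):
            v = getattr(self, fname)
            if v < 0 or v > self.n:
                raise FixtureError(
                    f"{name}.{fname}={v} outside [0, n={self.n}]"
                )


@dataclass(frozen=True)
class FixtureSpec:
    """Exact-count specification of a deterministic cohort.

    One :class:`ClassCounts` per image class; scores and confidences are
    deterministic representatives (``score_positive`` for calls at/above the
    cutoff, ``score_negative`` below).
    """

    malignant: ClassCounts
    benign: ClassCounts
    no_lesion: ClassCounts
    score_positive: float = 0.9
    score_negative: float = 0.05
    confidence: ConfidenceModel = field(default_factory=ConfidenceModel)
    images_per_screening: float = 4021 / 2069

    def counts(self) -> dict[str, ClassCounts]:
        return {
            "malignant": self.malignant,
            "benign": self.benign,
            "no_lesion": self.no_lesion,
        }


def paper_fixture_spec() -> FixtureSpec:
    """The default exact-count specification matching the published test set.

    2289 malignant / 731 benign / 1001 no-lesion images; 165 detector false
    negatives (125/40 across malignant/benign, proportional split, floor for
    malignant) and 180 false positives; classifier calls 2040/249 on malignant
    and 572 benign-correct / 159 false-recall on benign; unassisted
    radiologist 2268 true recalls and 523 false recalls (220/303 across
    benign/no-lesion); detection review recovers every lesion. Size classes
    split 228 / 2792 (173/55 across malignant/benign).
    """
    return FixtureSpec(
        malignant=ClassCounts(
            n=2289,
            detector_negatives=125,
            classifier_positives=2040,
            rad_class_positives=2268,
            rad_detect_positives=2289,
            rad_assisted_positives=2097,
            lt1cm=173,
        ),
        benign=ClassCounts(
            n=731,
            detector_negatives=40,
            classifier_positives=159,
            rad_class_positives=220,
            rad_detect_positives=731,
            rad_assisted_positives=96,
            lt1cm=55,
        ),
        no_lesion=ClassCounts(
            n=1001,
            detector_negatives=821,
            classifier_positives=217,
            rad_class_positives=303,
            rad_detect_positives=0,
            rad_assisted_positives=131,
            lt1cm=0,
        ),
    )


def build_fixture(spec: FixtureSpec) -> pd.DataFrame:
    """Expand an exact-count specification into a deterministic cohort table.

    Marginal counts per (class x agent outcome) match the specification
    exactly; joint cells are filled by proportional largest-remainder
    apportionment, so no sampling is involved.

    Raises
    ------
    FixtureError
        If any cell count exceeds its marginal.
    """
    frames: list[pd.DataFrame] = []
    offset = 0
    for cname, cc in spec.counts().items():
        cc.validate(cname)
        if cc.n == 0:
            continue
        if cname == "no_lesion" and cc.lt1cm:
            raise FixtureError("no_lesion.lt1cm must be 0 (size defined on lesions)")

        det_sizes = np.array([cc.n - cc.detector_negatives, cc.detector_negatives])
        cls_pos = _apportion(cc.classifier_positives, det_sizes)

        # four (detector, classifier) cells per class
        cell_sizes = np.array(
            [
                cls_pos[0],
                det_sizes[0] - cls_pos[0],
                cls_pos[1],
                det_sizes[1] - cls_pos[1],
            ]
        )
        det_in_cell = np.array([True, True, False, False])
        clf_in_cell = np.array([True, False, True, False])

        rad_class = _apportion(cc.rad_class_positives, cell_sizes)
        rad_detect = _apportion(cc.rad_detect_positives, cell_sizes)
        rad_assist = _apportion(cc.rad_assisted_positives, cell_sizes)
        lt1 = _apportion(cc.lt1cm, cell_sizes)

        for j, m in enumerate(cell_sizes):
            if m == 0:
                continue
            idx = np.arange(m)
            has_lesion = cname != "no_lesion"
            truth = cname == "malignant"
            rc = idx < rad_class[j]
            frames.append(
                pd.DataFrame(
                    {
                        "image_id": [f"img{offset + i:06d}" for i in idx],
                        "center_id": 1,
                        "has_lesion": has_lesion,
                        "malignant": pd.array(
                            [truth if has_lesion else None] * m, dtype="boolean"
                        ),
                        "size_class": pd.array(
                            np.where(idx < lt1[j], "lt1cm", "ge1cm")
                            if has_lesion
                            else [None] * m,
                            dtype="string",
                        ),
                        "detector_flag": det_in_cell[j],
                        "classifier_score": np.where(
                            clf_in_cell[j], spec.score_positive, spec.score_negative
                        ),
                        "rad_detect_flag": idx < rad_detect[j],
                        "rad_class_flag": rc,
                        "rad_assisted_flag": idx < rad_assist[j],
                        "rad_confidence": _confidence(
                            spec.confidence, rc, np.full(m, truth)
                        ),
                    }
                )
            )
            offset += m

    df = pd.concat(frames, ignore_index=True)
    # deterministic screening grouping: pairs first, then singletons
    n = len(df)
    n_screenings = int(round(n / spec.images_per_screening))
    n_two = int(np.clip(n - n_screenings, 0, n // 2))
    sids = np.empty(n, dtype=np.int64)
    sids[: 2 * n_two] = np.repeat(np.arange(n_two), 2)
    sids[2 * n_two :] = np.arange(n_two, n_two + (n - 2 * n_two))
    df["screening_id"] = [f"scr{s:06d}" for s in sids]
    return df[COHORT_COLUMNS].reset_index(drop=True)


def paper_fixture() -> pd.DataFrame:
    """Deterministic 4021-image cohort matching the published test set."""
    return build_fixture(paper_fixture_spec())


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_cohort(cohort: pd.DataFrame) -> list[dict]:
    """Report invariant violations in a cohort table.

    Returns a list of ``{"image_id": ..., "violation": ...}`` records; an
    empty list means the table is valid. Never raises on content problems.
    """
    report: list[dict] = []

    def flag(mask: np.ndarray, message: str) -> None:
        for img in cohort.loc[np.asarray(mask, dtype=bool), "image_id"]:
            report.append({"image_id": img, "violation": message})

    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        return [{"image_id": None, "violation": f"missing columns: {missing}"}]

    dup = cohort["image_id"].duplicated(keep=False)
    flag(dup.to_numpy(), "duplicate image_id")

    has = cohort["has_lesion"].astype(bool).to_numpy()
    mal_def = cohort["malignant"].notna().to_numpy()
    size_def = cohort["size_class"].notna().to_numpy()
    flag(has & ~mal_def, "malignant undefined on lesion image")
    flag(~has & mal_def, "malignant defined on no-lesion image")
    flag(has & ~size_def, "size_class undefined on lesion image")
    flag(~has & size_def, "size_class defined on no-lesion image")

    bad_size = size_def & ~cohort["size_class"].isin(SIZE_CLASSES).to_numpy()
    flag(bad_size, "size_class outside {lt1cm, ge1cm}")

    for col in ("classifier_score", "rad_confidence"):
        vals = cohort[col].to_numpy(dtype=float)
        flag((vals < 0) | (vals > 1) | ~np.isfinite(vals), f"{col} outside [0, 1]")

    return report
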