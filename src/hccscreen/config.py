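"""Configuration models for cohort synthesis and pipeline runs.

All knobs that shape a synthetic screening cohort live here. Defaults encode
the published test-set conditions: 4021 images split 2289 malignant / 731
benign / 1001 no-lesion, the component operating points (detector 0.941/0.833,
classifier 0.891/0.783 at cutoff 0.2, radiologist 0.991/0.698), and the margin
and alpha conventions of the statistical analysis.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

#: Canonical strategy identifiers, in reporting order.
STRATEGY_IDS = ("original", "s1", "s2", "s3", "s4")

#: Image classes used throughout the package.
CLASSES = ("malignant", "benign", "no_lesion")


class OperatingPoint(BaseModel):
    """A (sensitivity, specificity) pair for a binary decision agent."""

    sensitivity: float = Field(ge=0.0, le=1.0)
    specificity: float = Field(ge=0.0, le=1.0)

    model_config = {"frozen": True}


class ConfidenceModel(BaseModel):
    """Two-point model for the recall probability a radiologist would report.

    A call that agrees with ground truth is made with high confidence
    ``concordant``; a call that disagrees is made with the milder confidence
    ``discordant``. The stored value is always P(recall): a confident
    no-recall call maps to ``1 - concordant``.
    """

    concordant: float = Field(default=0.95, gt=0.5, le=1.0)
    discordant: float = Field(default=0.60, gt=0.5, le=1.0)

    model_config = {"frozen": True}

    def p_recall(self, call_recall: bool, correct: bool) -> float:
        c = self.concordant if correct else self.discordant
        return c if call_recall else 1.0 - c


class CohortConfig(BaseModel):
    """Parameters of the stochastic cohort generator.

    Class fractions default to the test-set composition; operating points
    default to the published component performance. ``score_shape`` is the
    first Beta shape parameter of the classifier score laws (the second is
    solved so the law hits the configured sensitivity/specificity exactly at
    the cutoff).
    """

    n_images: int = Field(default=4021, gt=0)
    frac_malignant: float = Field(default=2289 / 4021, ge=0.0, le=1.0)
    frac_benign: float = Field(default=731 / 4021, ge=0.0, le=1.0)
    frac_no_lesion: float = Field(default=1001 / 4021, ge=0.0, le=1.0)
    size_fraction_lt1cm: float = Field(default=228 / 3020, ge=0.0, le=1.0)

    detector: OperatingPoint = OperatingPoint(sensitivity=0.941, specificity=0.833)
    classifier: OperatingPoint = OperatingPoint(sensitivity=0.891, specificity=0.783)
    radiologist_original: OperatingPoint = OperatingPoint(
        sensitivity=0.991, specificity=0.698
    )
    radiologist_detect_review: OperatingPoint = OperatingPoint(
        sensitivity=1.0, specificity=1.0
    )
    radiologist_assisted: OperatingPoint = OperatingPoint(
        sensitivity=0.916, specificity=0.869
    )

    cutoff: float = Field(default=0.2, gt=0.0, lt=1.0)
    score_shape: float = Field(default=2.0, gt=0.0)
    confidence: ConfidenceModel = ConfidenceModel()

    #: Mean images per screening visit; the test set has 4021/2069 ~ 1.94.
    images_per_screening: float = Field(default=4021 / 2069, ge=1.0, le=2.0)
    n_centers: int = Field(default=8, gt=0)
    seed: int

    @model_validator(mode="after")
    def _fractions_sum_to_one(self) -> "CohortConfig":
        total = self.frac_malignant + self.frac_benign + self.frac_no_lesion
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                "class fractions frac_malignant + frac_benign + frac_no_lesion "
                f"must sum to 1 (got {total!r})"
            )
        return self

    @property
    def class_fractions(self) -> dict[str, float]:
        return {
            "malignant": self.frac_malignant,
            "benign": self.frac_benign,
            "no_lesion": self.frac_no_lesion,
        }


class RunConfig(BaseModel):
    """Top-level configuration of a pipeline run (``simulate`` subcommand)."""

    mode: Literal["simulate", "fixture"] = "fixture"
    fixture_name: str = "paper_fixture"
    cohort: Optional[CohortConfig] = None
    strategies: list[str] = Field(default_factory=lambda: list(STRATEGY_IDS))
    cutoff: float = Field(default=0.2, gt=0.0, lt=1.0)
    entropy_threshold: float = Field(default=0.1, gt=0.0)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    relative_sensitivity_margin: float = Field(default=0.05, gt=0.0, lt=1.0)
    absolute_specificity_margin: float = Field(default=0.01, gt=0.0, lt=1.0)
    bonferroni_n: Optional[int] = Field(default=None, gt=0)
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        unknown = [s for s in self.strategies if s not in STRATEGY_IDS]
        if unknown:
            raise ValueError(f"unknown strategies: {unknown}")
        if not self.strategies:
            raise ValueError("strategies must not be empty")
        if self.mode == "simulate":
            if self.cohort is None:
                raise ValueError("mode 'simulate' requires a cohort configuration")
            if self.seed is None and self.cohort.seed is None:
                raise ValueError("mode 'simulate' requires a seed")
        return self
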