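import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hccscreen as hs

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_cohort() -> pd.DataFrame:
    """The deterministic published-test-set cohort (4021 images)."""
    return hs.paper_fixture()


@pytest.fixture(scope="session")
def fixture_decisions(fixture_cohort) -> dict[str, pd.DataFrame]:
    return {
        sid: hs.apply_strategy(fixture_cohort, sid, cutoff=0.2)
        for sid in hs.STRATEGY_IDS
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240321)


def random_cohort(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Small unconstrained cohort for property checks (all agent columns)."""
    cls = rng.integers(0, 3, size=n)  # 0 malignant, 1 benign, 2 none
    has = cls < 2
    return pd.DataFrame(
        {
            "image_id": [f"r{i:04d}" for i in range(n)],
            "screening_id": [f"s{i:04d}" for i in range(n)],
            "center_id": 1,
            "has_lesion": has,
            "malignant": pd.array(
                [bool(c == 0) if h else None for c, h in zip(cls, has)],
                dtype="boolean",
            ),
            "size_class": pd.array(
                [("lt1cm" if rng.random() < 0.1 else "ge1cm") if h else None
                 for h in has],
                dtype="string",
            ),
            "detector_flag": rng.random(n) < 0.5,
            "classifier_score": rng.random(n),
            "rad_detect_flag": rng.random(n) < 0.5,
            "rad_class_flag": rng.random(n) < 0.5,
            "rad_assisted_flag": rng.random(n) < 0.5,
            "rad_confidence": rng.random(n),
        },
        columns=hs.COHORT_COLUMNS,
    )
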