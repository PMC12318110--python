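"""Decision workflows: flowchart oracle equivalence, workload accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import hccscreen as hs
from hccscreen.strategies import JoinError, SchemaError, StrategyError

from _oracles import strategy_oracle_row
from conftest import random_cohort


def _assert_matches_oracle(cohort: pd.DataFrame, cutoff: float = 0.2):
    for sid in hs.STRATEGY_IDS:
        got = hs.apply_strategy(cohort, sid, cutoff=cutoff)
        for i, (_, row) in enumerate(cohort.iterrows()):
            exp = strategy_oracle_row(row.to_dict(), sid, cutoff)
            g = got.iloc[i]
            assert bool(g.recall) == exp["recall"], (sid, i)
            assert int(g.detection_reads) == exp["det_reads"], (sid, i)
            assert int(g.classification_reads) == exp["cls_reads"], (sid, i)
            assert g.recall_prob == pytest.approx(exp["prob"]), (sid, i)
            assert g.deciding_agent == exp["agent"], (sid, i)


def _single_image_cohorts():
    """Every combination of agent outcomes for a one-image cohort."""
    rows = []
    for cls in ("malignant", "benign", "no_lesion"):
        for det in (False, True):
            for hi_score in (False, True):
                for rad_det in (False, True):
                    for rad_cls in (False, True):
                        for rad_ast in (False, True):
                            has = cls != "no_lesion"
                            rows.append(
                                {
                                    "image_id": "x0",
                                    "screening_id": "s0",
                                    "center_id": 1,
                                    "has_lesion": has,
                                    "malignant": (cls == "malignant") if has else None,
                                    "size_class": "ge1cm" if has else None,
                                    "detector_flag": det,
                                    "classifier_score": 0.8 if hi_score else 0.1,
                                    "rad_detect_flag": rad_det,
                                    "rad_class_flag": rad_cls,
                                    "rad_assisted_flag": rad_ast,
                                    "rad_confidence": 0.7,
                                }
                            )
    return rows


class TestOracleEquivalence:
    def test_all_single_image_outcome_combinations(self):
        for row in _single_image_cohorts():
            cohort = pd.DataFrame([row]).astype({"malignant": "boolean"})
            cohort["size_class"] = pd.array(cohort["size_class"], dtype="string")
            _assert_matches_oracle(cohort)

    def test_random_small_cohorts(self, rng):
        for _ in range(25):
            _assert_matches_oracle(random_cohort(rng, int(rng.integers(1, 13))))

    def test_cutoff_is_respected(self, rng):
        cohort = random_cohort(rng, 12)
        _assert_matches_oracle(cohort, cutoff=0.5)


class TestWorkload:
    def test_fixture_workload_identities(self, fixture_decisions):
        assert hs.count_workload(fixture_decisions["original"])["total"] == 4021
        assert hs.count_workload(fixture_decisions["s1"])["total"] == 0
        s2 = hs.count_workload(fixture_decisions["s2"])
        assert s2 == {"total": 986, "detection_reads": 986, "classification_reads": 0}

    def test_strategy3_reads_both_stages(self, fixture_decisions):
        s3 = hs.count_workload(fixture_decisions["s3"])
        assert s3["detection_reads"] == 986
        assert s3["classification_reads"] == 3200
        assert s3["total"] == 4186  # exceeds the cohort size: two-stage reads

    def test_reads_bounded_by_two_per_image(self, fixture_decisions):
        for dec in fixture_decisions.values():
            per_img = dec.detection_reads + dec.classification_reads
            assert (per_img <= 2).all()

    def test_original_reads_exactly_once(self, fixture_decisions):
        dec = fixture_decisions["original"]
        assert ((dec.detection_reads + dec.classification_reads) == 1).all()

    def test_all_confident_positive_degenerate_case(self):
        n = 6
        cohort = pd.DataFrame(
            {
                "image_id": [f"i{k}" for k in range(n)],
                "screening_id": "s0",
                "center_id": 1,
                "has_lesion": True,
                "malignant": pd.array([True] * n, dtype="boolean"),
                "size_class": pd.array(["ge1cm"] * n, dtype="string"),
                "detector_flag": True,
                "classifier_score": 1.0,
                "rad_detect_flag": True,
                "rad_class_flag": True,
                "rad_assisted_flag": True,
                "rad_confidence": 0.95,
            }
        )
        dec = hs.apply_strategy(cohort, "s4")
        assert dec.recall.all()
        assert hs.count_workload(dec)["total"] == 0

    def test_mixed_strategies_rejected(self, fixture_decisions):
        mixed = pd.concat(
            [fixture_decisions["s1"], fixture_decisions["s2"]], ignore_index=True
        )
        with pytest.raises(StrategyError):
            hs.count_workload(mixed)


class TestProperties:
    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    def test_raising_score_never_revokes_recall(self, low, high):
        lo, hi = sorted((low, high))
        base = {
            "image_id": "a", "screening_id": "s", "center_id": 1,
            "has_lesion": True, "malignant": True, "size_class": "ge1cm",
            "detector_flag": True, "rad_detect_flag": True,
            "rad_class_flag": False, "rad_assisted_flag": False,
            "rad_confidence": 0.6,
        }
        for sid in ("s1", "s2", "s4"):
            verdicts = []
            for score in (lo, hi):
                cohort = pd.DataFrame([{**base, "classifier_score": score}])
                cohort["malignant"] = cohort["malignant"].astype("boolean")
                cohort["size_class"] = pd.array(cohort["size_class"], dtype="string")
                verdicts.append(bool(hs.apply_strategy(cohort, sid).recall.iloc[0]))
            assert verdicts[0] <= verdicts[1], sid

    def test_s1_recalls_nested_in_s4(self, rng):
        for _ in range(10):
            cohort = random_cohort(rng, 40)
            r1 = hs.apply_strategy(cohort, "s1").recall.to_numpy()
            r4 = hs.apply_strategy(cohort, "s4").recall.to_numpy()
            assert not (r1 & ~r4).any()

    def test_s1_uses_no_radiologist(self, rng):
        dec = hs.apply_strategy(random_cohort(rng, 30), "s1")
        assert hs.count_workload(dec)["total"] == 0


class TestRecallLabels:
    def test_toy_join_and_order_invariance(self, rng):
        cohort = random_cohort(rng, 3)
        dec = hs.apply_strategy(cohort, "original")
        v1, t1 = hs.recall_labels(dec, cohort)
        assert len(v1) == len(t1) == 3
        shuffled = dec.sample(frac=1.0, random_state=0).reset_index(drop=True)
        v2, t2 = hs.recall_labels(shuffled, cohort)
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(t1, t2)

    def test_unmatched_ids_listed(self, rng):
        cohort = random_cohort(rng, 4)
        dec = hs.apply_strategy(cohort, "s1").iloc[:3]
        with pytest.raises(JoinError, match="r0003"):
            hs.recall_labels(dec, cohort)

    def test_fixture_original_recall_count(self, fixture_cohort, fixture_decisions):
        v, t = hs.recall_labels(fixture_decisions["original"], fixture_cohort)
        assert int(v.sum()) == 2791  # 0.694 of 4021


class TestErrors:
    def test_unknown_strategy(self, fixture_cohort):
        with pytest.raises(StrategyError, match="s9"):
            hs.apply_strategy(fixture_cohort, "s9")

    def test_missing_column_named(self, fixture_cohort):
        broken = fixture_cohort.drop(columns=["rad_assisted_flag"])
        with pytest.raises(SchemaError, match="rad_assisted_flag"):
            hs.apply_strategy(broken, "s3")
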