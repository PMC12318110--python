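"""Performance measures: confusion metrics, AUCs, workload reduction."""

import numpy as np
import pytest

import hccscreen as hs
from hccscreen.metrics import ConfusionTable, UndefinedMetricError

from _oracles import pairwise_auc
from conftest import random_cohort


class TestConfusion:
    def test_toy_counts(self):
        conf = hs.confusion([1, 0], [1, 0])
        assert (conf.tp, conf.tn, conf.fp, conf.fn) == (1, 1, 0, 0)

    def test_fixture_original_cells(self, fixture_cohort, fixture_decisions):
        v, t = hs.recall_labels(fixture_decisions["original"], fixture_cohort)
        conf = hs.confusion(v, t)
        assert conf.tp == 2268 and conf.fp == 523

    def test_all_recall_degenerate_policy(self, fixture_cohort):
        t = hs.recall_truth(fixture_cohort)
        conf = hs.confusion(np.ones_like(t), t)
        assert (conf.tp, conf.fp, conf.tn, conf.fn) == (2289, 1732, 0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            hs.confusion([1, 0], [1])


class TestPerformance:
    def test_detector_fixture_accuracy(self):
        conf = ConfusionTable(tp=3020 - 165, fp=180, tn=1001 - 180, fn=165)
        perf = hs.performance(conf)
        assert hs.round_half_away(perf.accuracy) == 0.914
        assert conf.tp + conf.tn == 3676

    def test_original_recall_rate(self):
        conf = ConfusionTable(tp=2268, fp=523, fn=21, tn=1209)
        perf = hs.performance(conf)
        assert hs.round_half_away(perf.recall_rate) == 0.694

    def test_perfect_confusion(self):
        perf = hs.performance(ConfusionTable(tp=5, fp=0, tn=5, fn=0))
        assert perf.sensitivity == perf.specificity == perf.accuracy == 1.0

    def test_interval_brackets_point(self, fixture_cohort, fixture_decisions):
        v, t = hs.recall_labels(fixture_decisions["s2"], fixture_cohort)
        perf = hs.performance(hs.confusion(v, t))
        for metric in ("sensitivity", "specificity", "accuracy",
                       "recall_rate", "false_positive_rate"):
            lo, hi = getattr(perf, f"{metric}_ci")
            assert lo <= getattr(perf, metric) <= hi

    def test_fpr_complements_specificity(self, fixture_cohort, fixture_decisions):
        v, t = hs.recall_labels(fixture_decisions["s4"], fixture_cohort)
        perf = hs.performance(hs.confusion(v, t))
        assert perf.false_positive_rate + perf.specificity == pytest.approx(1.0)

    def test_recall_rate_integer_identity(self, fixture_cohort, fixture_decisions):
        v, t = hs.recall_labels(fixture_decisions["s1"], fixture_cohort)
        conf = hs.confusion(v, t)
        perf = hs.performance(conf)
        assert round(perf.recall_rate * conf.n) == conf.tp + conf.fp

    def test_zero_denominator_names_metric(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            hs.performance(ConfusionTable(tp=0, fp=1, tn=1, fn=0))


class TestAuc:
    def test_printed_operating_points(self):
        auc = hs.single_point_auc(hs.OperatingPoint(sensitivity=0.991, specificity=0.698))
        assert hs.round_half_away(auc) == 0.845
        auc = hs.single_point_auc(hs.OperatingPoint(sensitivity=0.956, specificity=0.787))
        assert hs.round_half_away(auc) == 0.872

    def test_perfect_point(self):
        assert hs.single_point_auc(hs.OperatingPoint(sensitivity=1, specificity=1)) == 1.0

    def test_empirical_perfect_separation(self):
        assert hs.empirical_roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_empirical_null_is_half(self, rng):
        n = 4000
        scores = rng.random(n)
        truths = rng.random(n) < 0.5
        se = np.sqrt(1 / 12 / truths.sum() + 1 / 12 / (~truths).sum())
        assert abs(hs.empirical_roc_auc(scores, truths) - 0.5) < 3 * se

    def test_six_point_toy_set(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.1]
        truths = [1, 1, 1, 0, 0, 0]
        assert hs.empirical_roc_auc(scores, truths) == pytest.approx(8 / 9)
        assert pairwise_auc(scores, truths) == pytest.approx(8 / 9)

    def test_single_point_equals_binary_score_auc(self, rng):
        for _ in range(5):
            cohort = random_cohort(rng, 200)
            dec = hs.apply_strategy(cohort, "s2")
            v, t = hs.recall_labels(dec, cohort)
            if t.all() or not t.any():
                continue
            conf = hs.confusion(v, t)
            perf = hs.performance(conf)
            op = hs.OperatingPoint(
                sensitivity=perf.sensitivity, specificity=perf.specificity
            )
            assert hs.single_point_auc(op) == pytest.approx(
                hs.empirical_roc_auc(v.astype(float), t)
            )

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            hs.empirical_roc_auc([0.1, 0.9], [1, 1])


class TestWorkloadReduction:
    @pytest.mark.parametrize(
        "w, ref, expected",
        [(986, 4021, 0.755), (4021, 4021, 0.0), (4186, 4021, -0.041),
         (1829, 4021, 0.545), (0, 4021, 1.0)],
    )
    def test_printed_workloads(self, w, ref, expected):
        assert hs.round_half_away(hs.workload_reduction(w, ref)) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            hs.workload_reduction(1, 0)


class TestSubgroups:
    def test_fixture_partition_sizes(self, fixture_cohort):
        lesion = fixture_cohort[fixture_cohort.has_lesion]
        sizes = lesion.size_class.value_counts()
        assert sizes["lt1cm"] == 228 and sizes["ge1cm"] == 2792

    def test_subgroup_metrics_exist_per_group(self, fixture_cohort, fixture_decisions):
        out = hs.subgroup_performance(fixture_cohort, fixture_decisions["s4"])
        assert set(out) == {"lt1cm", "ge1cm"}

    def test_weighted_sensitivities_aggregate(self, fixture_cohort, fixture_decisions):
        out = hs.subgroup_performance(fixture_cohort, fixture_decisions["s2"])
        v, t = hs.recall_labels(fixture_decisions["s2"], fixture_cohort)
        overall = hs.performance(hs.confusion(v, t)).sensitivity
        lesion = fixture_cohort.has_lesion.to_numpy()
        size = fixture_cohort.size_class.fillna("").to_numpy(dtype=object)
        truth = hs.recall_truth(fixture_cohort)
        weights = {g: int((truth & lesion & (size == g)).sum()) for g in out}
        agg = sum(out[g].sensitivity * weights[g] for g in out) / sum(weights.values())
        assert agg == pytest.approx(overall)

    def test_single_group_equals_lesion_cohort(self, rng):
        cohort = random_cohort(rng, 60)
        cohort["size_class"] = cohort["size_class"].mask(
            cohort["has_lesion"], "ge1cm"
        )
        dec = hs.apply_strategy(cohort, "s1")
        out = hs.subgroup_performance(cohort, dec)
        assert set(out) == {"ge1cm"}
        lesion = cohort.has_lesion.to_numpy()
        v, t = hs.recall_labels(dec, cohort)
        expect = hs.performance(hs.confusion(v[lesion], t[lesion]))
        assert out["ge1cm"].sensitivity == pytest.approx(expect.sensitivity)
        assert out["ge1cm"].specificity == pytest.approx(expect.specificity)


class TestRounding:
    @pytest.mark.parametrize(
        "x, nd, expected",
        [(0.8445, 3, 0.845), (0.8715, 3, 0.872), (-0.0405, 3, -0.041),
         (0.7547873, 3, 0.755), (0.5451380, 3, 0.545), (0.0796431, 4, 0.0796)],
    )
    def test_half_away_from_zero(self, x, nd, expected):
        assert hs.round_half_away(x, nd) == expected
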