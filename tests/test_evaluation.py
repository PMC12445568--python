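import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thalscreen.classifier import DominanceRuleClassifier
from thalscreen.evaluation import (
    MentzerBaseline,
    confusion_and_metrics,
    paired_t_test,
    repeated_runs,
    roc_pr,
    split,
)
from thalscreen.simulate import SimulationConfig, generate_dataset


class TestSplit:
    def test_sizes_and_determinism(self):
        frame = pd.DataFrame({"a": range(10), "decision": [0] * 8 + [1] * 2})
        train, test = split(frame, 0.8, seed=0)
        assert len(train) == 8 and len(test) == 2
        train2, test2 = split(frame, 0.8, seed=0)
        assert list(train.index) == list(train2.index)

    def test_partition_property(self):
        frame = pd.DataFrame({"a": range(37), "decision": [0, 1] * 18 + [0]})
        train, test = split(frame, 0.8, seed=3)
        assert set(train.index) | set(test.index) == set(frame.index)
        assert not set(train.index) & set(test.index)

    def test_small_table_refused(self):
        with pytest.raises(ValueError, match="at least 2"):
            split(pd.DataFrame({"a": [1], "decision": [0]}))

    def test_bad_fraction(self):
        frame = pd.DataFrame({"a": range(4), "decision": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="train_fraction"):
            split(frame, 1.0)


class TestMetrics:
    def test_perfect_predictions(self):
        truth = [0, 0, 1, 1, 0]
        report = confusion_and_metrics(truth, truth)
        assert report.accuracy == 1.0
        for cls in (0, 1):
            for key in ("precision", "recall", "f1", "specificity"):
                assert report.per_class[cls][key] == 1.0

    def test_all_majority_on_imbalanced_split(self):
        truth = [0] * 83 + [1] * 17
        pred = [0] * 100
        report = confusion_and_metrics(truth, pred)
        assert report.accuracy == pytest.approx(0.83)
        assert report.per_class[1]["recall"] == 0.0
        assert report.per_class[0]["recall"] == 1.0

    def test_hand_built_confusion(self):
        """TP=3, FP=1, FN=2, TN=4 for the positive class."""
        truth = [1] * 3 + [0] + [1] * 2 + [0] * 4
        pred = [1] * 3 + [1] + [0] * 2 + [0] * 4
        report = confusion_and_metrics(truth, pred)
        c1 = report.per_class[1]
        assert c1["precision"] == pytest.approx(0.75)
        assert c1["recall"] == pytest.approx(0.6)
        assert c1["support"] == 5
        assert report.per_class[0]["specificity"] == pytest.approx(0.6)

    def test_cross_class_identities(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 2, 60)
        pred = rng.integers(0, 2, 60)
        report = confusion_and_metrics(truth, pred)
        for cls in (0, 1):
            c = report.per_class[cls]
            assert c["recall"] == pytest.approx(report.per_class[1 - cls]["specificity"])
            assert c["fpr"] + c["specificity"] == pytest.approx(1.0)
        # weighted averages reproduce from per-class values and supports
        supports = np.array([report.per_class[c]["support"] for c in (0, 1)])
        for key in ("precision", "recall", "f1"):
            manual = np.average(
                [report.per_class[c][key] for c in (0, 1)], weights=supports
            )
            assert report.weighted[key] == pytest.approx(manual)

    def test_label_validation(self):
        with pytest.raises(ValueError, match="labels outside"):
            confusion_and_metrics([0, 2], [0, 1])
        with pytest.raises(ValueError, match="equal length"):
            confusion_and_metrics([0, 1], [0, 1, 1])


class TestRocPr:
    def test_perfect_ranking(self):
        out = roc_pr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert out["roc_auc"] == 1.0

    def test_constant_scores(self):
        out = roc_pr([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert out["roc_auc"] == 0.5

    def test_six_point_hand_computed(self):
        """Scores 1..6 with labels 0,0,1,0,1,1: AUC = (number of concordant
        pairs)/(pos*neg) = 8/9 by direct enumeration."""
        truth = [0, 0, 1, 0, 1, 1]
        scores = [1, 2, 3, 4, 5, 6]
        out = roc_pr(truth, scores)
        assert out["roc_auc"] == pytest.approx(8 / 9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        truth = rng.integers(0, 2, 50)
        truth[0], truth[1] = 0, 1
        s = rng.random(50)
        a = roc_pr(truth, s)["roc_auc"]
        b = roc_pr(truth, np.exp(3 * s))["roc_auc"]
        assert a == pytest.approx(b)

    def test_one_class_refused(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_pr([1, 1], [0.2, 0.4])
        with pytest.raises(ValueError, match="finite"):
            roc_pr([0, 1], [np.inf, 0.4])


class TestPairedTTest:
    def test_identical_samples_degenerate_tie(self):
        res = paired_t_test([0.9, 0.8, 0.85], [0.9, 0.8, 0.85])
        assert res.degenerate and res.t_statistic == 0.0 and res.p_value == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_t_test([0.9, 0.9, 0.9, 0.9], [0.8, 0.8, 0.8, 0.8])
        assert res.degenerate and np.isinf(res.t_statistic) and res.p_value == 0.0

    def test_textbook_five_pairs(self):
        """Hand computation: d = (2, 4, 2, 4, 3), mean 3, sd 1,
        t = 3 / (1/sqrt(5)) = 6.7082."""
        a = [12.0, 15.0, 11.0, 16.0, 14.0]
        b = [10.0, 11.0, 9.0, 12.0, 11.0]
        res = paired_t_test(a, b)
        assert res.t_statistic == pytest.approx(6.7082, abs=5e-5)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(6.70820, df=4), rel=1e-4
        )

    def test_equals_one_sample_test_on_differences(self):
        rng = np.random.default_rng(77)
        a = rng.normal(0.9, 0.01, 12)
        b = rng.normal(0.89, 0.01, 12)
        res = paired_t_test(a, b)
        one_sample = stats.ttest_1samp(a - b, 0.0)
        assert abs(res.t_statistic - one_sample.statistic) < 1e-10
        assert abs(res.p_value - one_sample.pvalue) < 1e-10

    def test_sign_matches_mean_difference(self):
        res = paired_t_test([0.8, 0.82, 0.81], [0.9, 0.93, 0.91])
        assert res.t_statistic < 0 and res.mean_a < res.mean_b

    def test_input_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_t_test([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match="at least 2"):
            paired_t_test([1.0], [2.0])


@pytest.fixture(scope="module")
def planted():
    from thalscreen.rules import AT_LEAST, DecisionRule, ElementaryCondition, RuleSet

    rule = RuleSet(
        [
            DecisionRule(
                (
                    ElementaryCondition("mcv", "<=", 75.0),
                    ElementaryCondition("rbc", ">=", 5.0),
                ),
                AT_LEAST,
                1,
            )
        ]
    )
    frame = generate_dataset(SimulationConfig(n=250, seed=15, planted_rules=rule))
    return frame[["mcv", "rbc", "decision"]]


class TestRepeatedRuns:
    def test_harness_shape_and_determinism(self, planted):
        models = {"baseline": MentzerBaseline()}
        out1 = repeated_runs(models, planted, k=3, seeds=[0, 1, 2])
        out2 = repeated_runs(models, planted, k=3, seeds=[0, 1, 2])
        assert out1["baseline"].shape == (3,)
        assert np.array_equal(out1["baseline"], out2["baseline"])

    def test_drsa_beats_baseline_on_planted_rules(self, planted):
        """Labels are generated by a known two-condition rule, so the rule
        learner should dominate a single fixed-threshold index."""
        models = {
            "drsa": DominanceRuleClassifier(directions={"mcv": "cost", "rbc": "gain"}),
            "baseline": MentzerBaseline(),
        }
        out = repeated_runs(models, planted, k=3, seeds=[0, 1, 2])
        assert np.nanmean(out["drsa"]) >= np.nanmean(out["baseline"])

    def test_model_failure_recorded_as_nan(self, planted):
        class Broken:
            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

            def fit(self, X, y):
                raise RuntimeError("boom")

        with pytest.warns(UserWarning, match="failed"):
            out = repeated_runs({"broken": Broken()}, planted, k=2, seeds=[0, 1])
        assert np.isnan(out["broken"]).all()

    def test_k_validation(self, planted):
        with pytest.raises(ValueError, match="k must"):
            repeated_runs({}, planted, k=1)
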