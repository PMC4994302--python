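import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccxpen.evaluation import (
    rank_auc,
    reclassify,
    roc_curve,
    score_classification,
    subsample_auc_sensitivity,
)
from ccxpen.io_data import DrugBenchmark
from ccxpen.penalized import cv_lasso


def brute_force_auc(scores, labels):
    """Count concordant positive-negative pairs, ties half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestReclassify:
    def test_cutoff_rule(self):
        assert reclassify([3.0, 1.0, 0.1, 0.0]) == [
            "highly_suspected",
            "suspected",
            "other",
            "other",
        ]

    def test_exact_zero_lands_in_other(self):
        assert reclassify([0.0, -2.0]) == ["other", "other"]

    @pytest.mark.parametrize(
        "value,expected", [(0.45, "other"), (2.4, "suspected"), (2.4000001, "highly_suspected")]
    )
    def test_boundary_goes_to_lower_class(self, value, expected):
        assert reclassify([value]) == [expected]

    def test_non_finite_estimates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            reclassify([np.inf])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=10))
    def test_invariant_under_monotone_transform_fixing_cutoffs(self, values):
        # a strictly increasing map with fixed points at the cutoffs
        # cannot change any class assignment
        def transform(b):
            return 2.4 + 2 * (b - 2.4) if b > 2.4 else (
                0.45 + 0.5 * (b - 0.45) if b > 0.45 else b
            )

        assert reclassify(values) == reclassify([transform(v) for v in values])


class TestScoreClassification:
    def bench(self):
        return DrugBenchmark(
            ["a", "b", "c", "d"],
            ["highly_suspected", "suspected", "other", "other"],
        )

    def test_perfect_prediction(self):
        b = self.bench()
        res = score_classification(b.benchmark_class, b)
        assert res.total_correct == 4
        assert res.correct_by_class == {
            "highly_suspected": 1,
            "suspected": 1,
            "other": 2,
        }

    def test_confusion_sums_to_p_and_trace_is_total(self):
        b = self.bench()
        pred = ["suspected", "suspected", "highly_suspected", "other"]
        res = score_classification(pred, b)
        assert res.confusion.sum() == 4
        assert res.total_correct == int(np.trace(res.confusion)) == 2

    def test_invariant_to_drug_order(self):
        b = self.bench()
        pred = dict(zip(b.drug_names, ["other", "suspected", "other", "suspected"]))
        order1 = ["a", "b", "c", "d"]
        order2 = ["d", "c", "b", "a"]
        r1 = score_classification([pred[d] for d in order1], b, order1)
        r2 = score_classification([pred[d] for d in order2], b, order2)
        assert r1.total_correct == r2.total_correct
        assert r1.correct_by_class == r2.correct_by_class

    def test_drug_mismatch_raises(self):
        with pytest.raises(Exception, match="missing"):
            score_classification(["other"], self.bench(), ["unknown_drug"])


class TestAUC:
    def test_perfect_separation_gives_one(self):
        labels = [True, True, False, False]
        assert rank_auc([3, 2, 1, 0], labels) == 1.0

    def test_all_ties_give_half(self):
        assert rank_auc([1.0, 1.0, 1.0, 1.0], [True, True, False, False]) == 0.5

    def test_four_pair_example(self):
        # pairs: (3,2)+, (3,0)+, (1,2)-, (1,0)+ -> 3/4
        assert rank_auc([3, 1, 2, 0], [True, True, False, False]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            rank_auc([1, 2], [True, True])

    def test_rank_statistic_equals_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(4, 25)
            scores = rng.choice([-1.0, 0.0, 0.5, 1.3, 2.7], size=n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert rank_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels)
            )

    def test_rank_auc_equals_trapezoidal_roc_area(self, rng):
        # full threshold sweep (all distinct scores) integrates to the
        # same area as the rank statistic
        for _ in range(50):
            n = int(rng.integers(6, 20))
            scores = rng.normal(size=n).round(1)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            thr = np.r_[-np.inf, np.unique(scores), np.inf]
            pos, neg = labels.sum(), (~labels).sum()
            sens = [(scores[labels] > t).sum() / pos for t in thr]
            fpr = [(scores[~labels] > t).sum() / neg for t in thr]
            area = -np.trapezoid(sens, fpr)
            assert rank_auc(scores, labels) == pytest.approx(area)


class TestROCCurve:
    def bench(self):
        return DrugBenchmark(
            ["a", "b", "c", "d"],
            ["highly_suspected", "highly_suspected", "other", "other"],
        )

    def test_sensitivity_non_increasing_in_threshold(self):
        roc = roc_curve([3.1, 0.9, 2.0, 0.1], self.bench())
        assert np.all(np.diff(roc.sensitivity) <= 0)
        assert 0.0 <= roc.auc <= 1.0

    def test_positives_definition_changes_labels(self):
        bench = DrugBenchmark(
            ["a", "b", "c"], ["highly_suspected", "suspected", "other"]
        )
        est = [3.0, 1.0, 0.0]
        high = roc_curve(est, bench, "highly_only")
        both = roc_curve(est, bench, "highly_or_suspected")
        assert high.auc == 1.0 and both.auc == 1.0
        assert high.positives_definition != both.positives_definition

    def test_single_class_benchmark_rejected(self):
        bench = DrugBenchmark(["a", "b"], ["other", "other"])
        with pytest.raises(ValueError):
            roc_curve([1.0, 0.0], bench)


class TestSubsampleSensitivity:
    @staticmethod
    def lasso_fitter(data, seed):
        _, fit = cv_lasso(data, K=5, seed=seed, n_lambda=30)
        return fit.coefficients

    def test_full_fraction_single_draw_equals_full_data_auc(self, euroscar_like):
        data, bench = euroscar_like
        res = subsample_auc_sensitivity(
            data, bench, self.lasso_fitter, n_subsamples=1, fraction=1.0, seed=0
        )
        rng = np.random.default_rng(0)
        est = self.lasso_fitter(data, int(rng.integers(0, 2**31 - 1)))
        labels = np.array(
            [c == "highly_suspected" for c in bench.benchmark_class]
        )
        assert res["highly_only"]["values"][0] == pytest.approx(
            rank_auc(est, labels)
        )

    def test_lasso_auc_stable_under_subsampling(self, euroscar_like):
        data, bench = euroscar_like
        res = subsample_auc_sensitivity(
            data, bench, self.lasso_fitter, n_subsamples=15, fraction=0.75, seed=4
        )
        assert res["highly_only"]["iqr"] < 0.2
        assert res["highly_or_suspected"]["iqr"] < 0.2

    def test_deterministic_under_fixed_seed(self, euroscar_like):
        data, bench = euroscar_like
        kw = dict(n_subsamples=3, fraction=0.75, seed=9)
        a = subsample_auc_sensitivity(data, bench, self.lasso_fitter, **kw)
        b = subsample_auc_sensitivity(data, bench, self.lasso_fitter, **kw)
        assert a["highly_only"]["values"] == b["highly_only"]["values"]
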