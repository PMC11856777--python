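"""KU transforms, percentile thresholds, undetected fractions, metric oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kuq.ood_eval import (
    KuReport,
    OodBatch,
    auroc_auprc_with_range,
    ku_transform,
    percentile_threshold,
    run_ood_experiment,
    undetected_fraction,
)


class TestKuTransform:
    def test_fixed_points(self):
        assert ku_transform(0.1, "toy") == pytest.approx(0.0)
        assert ku_transform(0.0, "ehr") == pytest.approx(0.0)

    @pytest.mark.parametrize("variant", ["toy", "ehr"])
    def test_strictly_increasing(self, variant):
        sig = np.linspace(0.01, 5.0, 100)
        out = ku_transform(sig, variant)
        assert (np.diff(out) > 0).all()

    def test_toy_rejects_zero(self):
        with pytest.raises(ValueError):
            ku_transform(0.0, "toy")

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            ku_transform(1.0, "nope")


class TestPercentileThreshold:
    def test_exactly_ten_percent_above_for_distinct_values(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.linspace(0, 1, 100))
        thr = percentile_threshold(vals, 90.0)
        assert int((vals > thr).sum()) == 10

    def test_high_percentile_leaves_only_maximum_above(self):
        # as q -> 100 the strictly-above count shrinks to a single sample,
        # so the threshold approaches the maximum from below
        vals = np.arange(50.0)
        thr = percentile_threshold(vals, 99.999)
        assert (vals > thr).sum() == 1 and vals.max() > thr

    def test_all_equal_values_none_above(self):
        vals = np.full(40, 3.7)
        thr = percentile_threshold(vals, 90.0)
        assert int((vals > thr).sum()) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_threshold([], 90.0)

    @settings(deadline=None, max_examples=40)
    @given(n=st.integers(2, 300), q=st.sampled_from([50.0, 70.0, 90.0]))
    def test_nearest_rank_property(self, n, q):
        rng = np.random.default_rng(n)
        vals = rng.permutation(np.arange(n, dtype=float))  # distinct
        thr = percentile_threshold(vals, q)
        above = int((vals > thr).sum())
        assert above == int(np.ceil((1 - q / 100) * n))


class TestUndetectedFraction:
    def test_boundary_cases(self):
        assert undetected_fraction([1.0, 2.0], threshold=0.5) == 0.0
        assert undetected_fraction([1.0, 2.0], threshold=5.0) == 100.0

    def test_exact_arithmetic(self):
        ku = np.concatenate([np.zeros(337), np.ones(663)])
        assert undetected_fraction(ku, threshold=0.5) == pytest.approx(33.7)

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(1)
        test_ku = rng.standard_normal(500)
        ood_ku = rng.standard_normal(300) + 0.5
        fractions = [
            undetected_fraction(ood_ku, percentile_threshold(test_ku, q))
            for q in (50, 70, 90)
        ]
        assert fractions == sorted(fractions)  # lower q flags more OoD

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        test_sig = rng.uniform(0.01, 2.0, 400)
        ood_sig = rng.uniform(0.01, 3.0, 200)
        raw = undetected_fraction(ood_sig, percentile_threshold(test_sig, 90))
        for variant in ("toy", "ehr"):
            t = undetected_fraction(ku_transform(ood_sig, variant),
                                    percentile_threshold(
                                        ku_transform(test_sig, variant), 90))
            assert t == raw


class TestMetrics:
    def test_perfect_separation(self):
        scores = np.array([[0.1, 0.2, 0.8, 0.9]])
        labels = np.array([0, 0, 1, 1])
        out = auroc_auprc_with_range(scores, labels)
        assert out["auroc"] == 1.0 and out["auprc"] == 1.0

    def test_auroc_matches_pairwise_concordance(self):
        rng = np.random.default_rng(3)
        n = 200
        scores = rng.standard_normal(n)
        labels = rng.integers(0, 2, n)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        brute = wins / (len(pos) * len(neg))
        out = auroc_auprc_with_range(scores[None, :], labels)
        assert out["auroc"] == pytest.approx(brute, abs=1e-12)

    def test_auprc_matches_step_integration(self):
        rng = np.random.default_rng(4)
        n = 150
        scores = rng.standard_normal(n)
        labels = rng.integers(0, 2, n)
        # step integration: sum over thresholds of (recall_k - recall_{k-1}) * precision_k
        order = np.argsort(-scores)
        y = labels[order]
        tp = np.cumsum(y)
        precision = tp / np.arange(1, n + 1)
        recall = tp / y.sum()
        brute = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
        out = auroc_auprc_with_range(scores[None, :], labels)
        assert out["auprc"] == pytest.approx(brute, abs=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(5)
        n = 10000
        scores = rng.standard_normal(n)
        labels = rng.integers(0, 2, n)
        out = auroc_auprc_with_range(scores[None, :], labels)
        assert abs(out["auroc"] - 0.5) < 0.02

    def test_ranges_span_members(self):
        labels = np.array([0, 1, 0, 1, 1, 0])
        rng = np.random.default_rng(6)
        scores = rng.uniform(size=(4, 6))
        out = auroc_auprc_with_range(scores, labels)
        lo, hi = out["auroc_range"]
        assert lo <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc_auprc_with_range(np.ones((1, 4)), np.ones(4))

    def test_bootstrap_range_brackets_point_estimate(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 300)
        scores = labels + rng.standard_normal(300)  # informative, noisy
        out = auroc_auprc_with_range(scores[None, :], labels,
                                     range_method="bootstrap", n_boot=50)
        lo, hi = out["auroc_range"]
        assert lo <= out["auroc"] <= hi
        assert lo < hi  # resampling spread is nonzero
        again = auroc_auprc_with_range(scores[None, :], labels,
                                       range_method="bootstrap", n_boot=50)
        assert again["auroc_range"] == out["auroc_range"]  # seeded


class ConstantKuEstimator:
    """KU equal to a supplied score function; members echo the scores."""

    name = "stub"

    def __init__(self, ku_fn):
        self._ku_fn = ku_fn

    def ku(self, inputs):
        return self._ku_fn(*inputs)

    def prob(self, inputs):
        return np.clip(self._ku_fn(*inputs), 0.01, 0.99)

    def member_probs(self, inputs):
        return self.prob(inputs)[None, :]


class TestRunOodExperiment:
    def test_ood_identical_to_test_undetected_matches_percentile(self):
        rng = np.random.default_rng(7)
        sig = rng.uniform(0.1, 2.0, 500)
        labels = rng.integers(0, 2, 500)
        est = ConstantKuEstimator(lambda s: s)
        rep = run_ood_experiment(est, ((sig,), labels),
                                 [OodBatch("same", (sig,))],
                                 variant="ehr", q=70.0)
        assert rep.undetected_pct["same"] == pytest.approx(70.0, abs=0.5)

    def test_report_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        sig = rng.uniform(0.1, 2.0, 100)
        labels = rng.integers(0, 2, 100)
        est = ConstantKuEstimator(lambda s: s)
        rep = run_ood_experiment(
            est, ((sig,), labels),
            [OodBatch("x", (sig * 2,), distance=rng.uniform(0, 1, 100))],
            variant="ehr", q=70.0, experiment_id="stub-exp",
            metadata={"seed": 8})
        path = tmp_path / "rep.yaml"
        rep.save(path)
        again = KuReport.load(path)
        assert again == rep

    def test_distance_bins_cover_grid(self):
        rng = np.random.default_rng(9)
        sig = rng.uniform(0.1, 2.0, 200)
        labels = rng.integers(0, 2, 200)
        d = np.repeat(np.round(np.arange(0.1, 1.01, 0.1), 1), 20)
        est = ConstantKuEstimator(lambda s: s)
        rep = run_ood_experiment(est, ((sig,), labels),
                                 [OodBatch("g", (sig,), distance=d)],
                                 variant="ehr", q=70.0)
        assert len(rep.undetected_pct_by_bin["g"]) == 10
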