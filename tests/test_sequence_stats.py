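import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polarstates.data_model import LabelSequence
from polarstates.sequence_stats import (
    fdr_across_labels,
    frequency_difference,
    label_cluster_analysis,
    occurrence_frequency,
    permutation_cluster_test,
    split_by_prediction,
    time_resolved_onehot,
)


def _seq(labels, classes, names=("C+", "E-", "A+")):
    labels = np.asarray(labels)
    return LabelSequence(labels, 0.025 * np.arange(labels.shape[1]),
                         np.asarray(classes, dtype=object), names)


class TestOccurrenceFrequency:
    def test_three_trial_hand_count(self):
        seq = _seq([[0], [0], [1]], ["target", "target", "target"])
        fm = occurrence_frequency(seq)["target"]
        np.testing.assert_allclose(fm.freq[:, 0], [2 / 3, 1 / 3, 0.0])

    def test_single_trial_columns_are_one_hot(self):
        seq = _seq([[0, 2, 1]], ["target"])
        fm = occurrence_frequency(seq)["target"]
        np.testing.assert_array_equal(fm.freq.sum(axis=0), [1, 1, 1])
        assert set(np.unique(fm.freq)) == {0.0, 1.0}

    def test_columns_sum_to_one_without_sentinels(self, rng):
        labels = rng.integers(0, 3, size=(12, 6))
        seq = _seq(labels, ["standard"] * 7 + ["target"] * 5)
        for fm in occurrence_frequency(seq).values():
            np.testing.assert_allclose(fm.freq.sum(axis=0), 1.0, atol=1e-12)

    def test_sentinel_windows_reduce_column_sum(self):
        seq = _seq([[-1, 0], [0, 0]], ["target", "target"])
        fm = occurrence_frequency(seq)["target"]
        assert fm.freq[:, 0].sum() == pytest.approx(0.5)

    def test_onehot_equals_frequency(self, rng):
        labels = rng.integers(0, 3, size=(9, 4))
        seq = _seq(labels, ["standard"] * 4 + ["target"] * 5)
        oh = time_resolved_onehot(seq)
        fm = occurrence_frequency(seq)
        for cls in oh:
            np.testing.assert_allclose(oh[cls], fm[cls].freq, atol=1e-12)


class TestFrequencyDifference:
    def test_self_difference_is_zero(self, rng):
        labels = rng.integers(0, 3, size=(6, 5))
        fm = occurrence_frequency(_seq(labels, ["target"] * 6))["target"]
        assert np.all(frequency_difference(fm, fm) == 0.0)

    def test_antisymmetry(self, rng):
        a = occurrence_frequency(
            _seq(rng.integers(0, 3, (5, 4)), ["target"] * 5))["target"]
        b = occurrence_frequency(
            _seq(rng.integers(0, 3, (5, 4)), ["standard"] * 5))["standard"]
        np.testing.assert_allclose(frequency_difference(a, b),
                                   -frequency_difference(b, a))

    def test_shape_mismatch_rejected(self, rng):
        a = occurrence_frequency(
            _seq(rng.integers(0, 3, (5, 4)), ["target"] * 5))["target"]
        b = occurrence_frequency(
            _seq(rng.integers(0, 3, (5, 6)), ["standard"] * 5))["standard"]
        with pytest.raises(ValueError, match="shape"):
            frequency_difference(a, b)


class TestPermutationClusterTest:
    def test_zero_differences_give_no_clusters(self):
        clusters, _ = permutation_cluster_test(np.zeros((8, 30)), n_perm=100)
        assert clusters == []

    def test_planted_cluster_gets_minimal_attainable_p(self, rng):
        """A constant large effect in windows 10-20 with tiny noise yields
        exactly one cluster spanning those windows at the smallest p the
        sign-flip null can produce.

        Only a draw that flips every participant the same way can match the
        observed cluster mass (it reproduces |t| exactly); any mixed-sign
        draw collapses the effect. So p = (1 + k) / (1 + n_perm) with k the
        number of sign-symmetric draws, counted here from the same seeded
        RNG stream the test statistic uses.
        """
        n_perm, n_part = 200, 10
        diffs = 0.001 * rng.standard_normal((n_part, 40))
        diffs[:, 10:21] += 5.0
        clusters, _ = permutation_cluster_test(diffs, n_perm=n_perm, seed=0)
        spanning = [c for c in clusters if c.start <= 10 and c.end >= 20]
        assert len(spanning) == 1
        signs = np.random.default_rng(0).choice([-1.0, 1.0],
                                                size=(n_perm, n_part))
        k = int(np.sum(np.all(signs == signs[:, :1], axis=1)))
        assert spanning[0].p == pytest.approx((1 + k) / (1 + n_perm))
        assert spanning[0].p < 0.05

    def test_participant_order_invariance(self, rng):
        diffs = rng.standard_normal((9, 25)) + 0.6
        a, _ = permutation_cluster_test(diffs, n_perm=150, seed=5)
        perm = rng.permutation(9)
        b, _ = permutation_cluster_test(diffs[perm], n_perm=150, seed=5)
        assert [(c.start, c.end, c.p) for c in a] == \
               [(c.start, c.end, c.p) for c in b]

    def test_zero_variance_window_excluded(self, rng):
        diffs = rng.standard_normal((6, 10))
        diffs[:, 3] = 0.7  # identical across participants: t undefined
        _, excluded = permutation_cluster_test(diffs, n_perm=100, seed=1)
        assert excluded == [3]

    def test_circular_shift_scheme_runs(self, rng):
        diffs = rng.standard_normal((6, 20)) + 0.8
        clusters, _ = permutation_cluster_test(diffs, n_perm=100, seed=2,
                                               scheme="circular_shift")
        assert all(0.0 < c.p <= 1.0 for c in clusters)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="participants"):
            permutation_cluster_test(np.zeros((1, 10)), n_perm=100)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_across_labels([0.037])[0] == pytest.approx(0.037)

    def test_hand_bh_example(self):
        q = fdr_across_labels([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_across_labels([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=12))
    def test_matches_brute_force_step_up(self, ps):
        """BH step-up oracle: q_(i) = min over j>=i of m*p_(j)/j, capped at 1."""
        p = np.asarray(ps)
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate(
            (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        brute = np.empty(m)
        brute[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(fdr_across_labels(p), brute, atol=1e-12)


class TestLabelClusterAnalysis:
    def test_q_at_least_p_and_pooled_across_labels(self, rng):
        diffs = rng.standard_normal((4, 8, 30))
        diffs[0, :, 5:15] += 3.0
        res = label_cluster_analysis(diffs, n_perm=150, seed=0)
        assert any(c.label == 0 for c in res.clusters)
        for c in res.clusters:
            assert c.q is not None and c.q >= c.p - 1e-12

    def test_cluster_intervals_disjoint_per_label(self, rng):
        diffs = rng.standard_normal((3, 8, 40)) + 0.5
        res = label_cluster_analysis(diffs, n_perm=150, seed=3)
        for l in range(3):
            spans = sorted((c.start, c.end) for c in res.clusters if c.label == l)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2


class TestSplitByPrediction:
    def test_partition_sizes_and_edge_cases(self, rng):
        labels = rng.integers(0, 3, size=(8, 5))
        classes = ["standard"] * 4 + ["target"] * 4
        seq = _seq(labels, classes)
        pred = np.array(["standard"] * 8, dtype=object)
        correct, incorrect = split_by_prediction(seq, pred)
        assert correct.n_trials == 4 and incorrect.n_trials == 4
        all_right, none_wrong = split_by_prediction(seq, np.asarray(classes))
        assert all_right.n_trials == 8 and none_wrong.n_trials == 0

    def test_missing_predictions_rejected(self, rng):
        seq = _seq(rng.integers(0, 3, (4, 5)),
                   ["standard", "standard", "target", "target"])
        with pytest.raises(ValueError, match="prediction"):
            split_by_prediction(seq, np.array(["target"] * 3))
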