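import dataclasses
import itertools

import numpy as np
import pytest

from polarstates.classification import (
    ClassifResult,
    ConfusionCounts,
    CvSpec,
    ModelSpec,
    auc_score,
    compare_conditions,
    confusion_counts,
    f1_score,
    nested_cv_classify,
    temporal_generalization,
)
from polarstates.data_model import WindowSpec
from polarstates.labeling import LabelingConfig, balance_trials, label_epochs
from polarstates.synthetic import (
    null_oddball_config,
    polarity_contrast_config,
    simulate_session,
)
from polarstates.templates import expand_polarity

SMALL_RF = {"n_estimators": [50], "max_depth": [3, None]}
SMALL_LR = {"C": [1.0]}


def _labeled_session(cfg, polarity=True, step_ms=10.0, balance=False, seed=0):
    session = simulate_session(cfg)
    signed = expand_polarity(cfg.template_set)
    spec = WindowSpec(0.0, 0.4, 0.010, step_ms / 1000.0)
    seq = label_epochs(session.epochs, signed,
                       LabelingConfig(spec, polarity=polarity))
    return balance_trials(seq, seed=seed) if balance else seq


class TestF1:
    @pytest.mark.parametrize("tp,fp,tn,fn,expected", [
        (5, 0, 5, 0, 1.0),        # perfect classifier
        (2, 1, 0, 1, 2 / 3),      # hand arithmetic
        (0, 3, 0, 2, 0.0),        # zero true positives
    ])
    def test_known_values(self, tp, fp, tn, fn, expected):
        assert f1_score(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(expected)

    def test_undefined_denominator_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert f1_score(ConfusionCounts(0, 0, 4, 0)) == 0.0

    def test_matches_direct_formula_on_random_counts(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 20, size=4)
            if 2 * tp + fp + fn == 0:
                continue
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            harm = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert f1_score(c) == pytest.approx(harm)

    def test_confusion_from_predictions(self):
        truth = ["target", "target", "standard", "standard", "standard"]
        pred = ["target", "standard", "target", "standard", "standard"]
        c = confusion_counts(np.array(truth), np.array(pred))
        assert (c.TP, c.FP, c.TN, c.FN) == (1, 1, 2, 1)
        assert c.n == 5


class TestAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array(["target", "target", "standard", "standard"])
        assert auc_score(scores, truth) == 1.0

    def test_hand_pair_count(self):
        scores = np.array([0.6, 0.2, 0.5, 0.1])
        truth = np.array(["target", "target", "standard", "standard"])
        assert auc_score(scores, truth) == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        scores = np.full(6, 0.3)
        truth = np.array(["target"] * 3 + ["standard"] * 3)
        assert auc_score(scores, truth) == pytest.approx(0.5)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_score(np.array([0.1, 0.2]), np.array(["target", "target"]))

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(20):
            n_pos, n_neg = rng.integers(2, 10, size=2)
            scores = rng.integers(0, 5, size=n_pos + n_neg).astype(float)
            truth = np.array(["target"] * n_pos + ["standard"] * n_neg)
            pos = scores[:n_pos]
            neg = scores[n_pos:]
            wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
                       for p, q in itertools.product(pos, neg))
            assert auc_score(scores, truth) == pytest.approx(
                wins / (n_pos * n_neg))


class TestNestedCv:
    @pytest.fixture(scope="class")
    def null_seq(self):
        return _labeled_session(null_oddball_config(31, 50, 50))

    def test_fold_bookkeeping(self, null_seq):
        """Outer test folds are disjoint fifths; every trial is predicted
        exactly once out-of-fold."""
        res = nested_cv_classify(null_seq, ModelSpec("logistic_regression",
                                                     SMALL_LR))
        n = null_seq.n_trials
        assert sorted(np.bincount(res.fold_of_trial).tolist()) == [20] * 5
        assert res.fold_of_trial.min() >= 0
        assert not np.any(np.isnan(res.oof_score))
        assert all(p in ("standard", "target") for p in res.oof_pred)
        assert len(res.fold_f1) == 5
        assert res.mean_f1 == pytest.approx(float(np.mean(res.fold_f1)))

    def test_separable_polarity_contrast_reaches_perfect_f1(self):
        cfg = dataclasses.replace(polarity_contrast_config(17, 30, 30),
                                  noise_sd_uv=0.0)
        seq = _labeled_session(cfg)
        res = nested_cv_classify(seq, ModelSpec("logistic_regression", SMALL_LR))
        assert res.mean_f1 == 1.0
        assert res.auc == 1.0

    def test_kmeans_baseline_near_chance_on_null_data(self, null_seq):
        res = nested_cv_classify(null_seq, ModelSpec("kmeans_baseline"))
        assert 0.25 <= res.mean_f1 <= 0.75
        assert 0.3 <= res.auc <= 0.7

    def test_unbalanced_input_warns(self):
        seq = _labeled_session(null_oddball_config(5, 30, 10))
        with pytest.warns(UserWarning, match="unbalanced"):
            nested_cv_classify(seq, ModelSpec("logistic_regression", SMALL_LR))

    @pytest.mark.parametrize("family", ["random_forest", "gradient_boosting_xgb",
                                        "gradient_boosting_lgbm", "svm"])
    def test_all_supervised_families_run(self, family):
        cfg = polarity_contrast_config(23, 20, 20)
        seq = _labeled_session(cfg)
        grid = {"svm": {"C": [1], "kernel": ["linear"]},
                "random_forest": SMALL_RF,
                "gradient_boosting_xgb": {"learning_rate": [0.1]},
                "gradient_boosting_lgbm": {"learning_rate": [0.1]}}[family]
        res = nested_cv_classify(seq, ModelSpec(family, grid))
        assert res.mean_f1 > 0.9  # polarity contrast is easy when considered
        assert len(res.best_params) == 5


class TestTemporalGeneralization:
    def test_matrix_shape_trims_boundary_windows(self):
        cfg = polarity_contrast_config(41, 20, 20)
        session = simulate_session(cfg)
        signed = expand_polarity(cfg.template_set)
        spec = WindowSpec(-0.2, 0.4, 0.100, 0.025)
        seq = label_epochs(session.epochs, signed, LabelingConfig(spec))
        mat, starts = temporal_generalization(
            seq, ModelSpec("logistic_regression", SMALL_LR), CvSpec(seed=0),
            search=False)
        assert mat.shape == (seq.n_windows - 2, seq.n_windows - 2)
        assert starts.shape == (seq.n_windows - 2,)
        # the planted contrast is present at every window, so the diagonal
        # should decode far above chance on average
        assert np.mean(np.diag(mat)) > 0.8

    def test_too_few_windows_rejected(self, rng):
        from polarstates.data_model import LabelSequence

        seq = LabelSequence(rng.integers(0, 3, (10, 2)), [0.0, 0.025],
                            np.array(["standard"] * 5 + ["target"] * 5,
                                     dtype=object), ("A", "B", "C"))
        with pytest.raises(ValueError, match="3 windows"):
            temporal_generalization(seq)


class TestCompareConditions:
    def test_tidy_table_row_count(self):
        res = ClassifResult([0.5] * 5, 0.5, 0.5, [0.5] * 5, [{}] * 5,
                            np.array(["target"] * 10, dtype=object),
                            np.zeros(10), np.zeros(10, dtype=int))
        table = compare_conditions({
            ("5", "polar", "rf"): res, ("5", "non", "rf"): res,
            ("4", "polar", "rf"): res, ("4", "non", "rf"): res,
        })
        assert len(table) == 4 * 5
        summary = table.groupby(["variant", "polarity"])["f1"].mean()
        assert len(summary) == 4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no completed"):
            compare_conditions({})
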