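"""Metric formulas vs independent oracles; noise and condition protocols."""

import numpy as np
import pytest

from adsaf.config import DomainShiftParams, SyntheticSpec
from adsaf.evaluation import (
    add_gaussian_noise,
    compute_metrics,
    evaluate_conditions,
    roc_curve,
)
from adsaf.experiments import fast_train_config, small_model_config
from adsaf.synthetic import generate_dataset
from adsaf.training import split_subjectwise, train_model


def mann_whitney_auc(labels, scores):
    """Exhaustive pairwise-concordance oracle for the AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_predictions_score_one_everywhere(self):
        y = np.array([0, 1, 0, 1, 1])
        rep = compute_metrics(y, y, K=2)
        assert rep.accuracy == rep.f_score == rep.sensitivity == rep.specificity == 1.0
        assert rep.confusion.sum() == 5

    def test_printed_confusion_example_matches_formula_oracle(self):
        # TP=40, FN=10, TN=45, FP=5
        labels = np.array([1] * 50 + [0] * 50)
        preds = np.array([1] * 40 + [0] * 10 + [0] * 45 + [1] * 5)
        rep = compute_metrics(labels, preds, K=2)
        assert abs(rep.sensitivity - 0.800) < 1e-12
        assert abs(rep.specificity - 0.900) < 1e-12
        assert abs(rep.accuracy - 0.850) < 1e-12
        # F1 = 2 * precision * recall / (precision + recall) = 16/19
        assert abs(rep.f_score - 16.0 / 19.0) < 1e-12

    def test_all_positive_predictor_on_balanced_data(self):
        labels = np.array([0, 1] * 20)
        preds = np.ones(40, dtype=int)
        rep = compute_metrics(labels, preds, K=2)
        assert rep.accuracy == 0.5
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0    # class-1-positive convention

    def test_agrees_with_sklearn_on_random_pairs(self):
        from sklearn.metrics import (
            accuracy_score,
            confusion_matrix as sk_cm,
            f1_score,
            recall_score,
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, size=50)
            p = rng.integers(0, 2, size=50)
            if y.min() == y.max():
                continue
            rep = compute_metrics(y, p, K=2)
            assert np.array_equal(rep.confusion, sk_cm(y, p, labels=[0, 1]))
            assert abs(rep.accuracy - accuracy_score(y, p)) < 1e-12
            assert abs(rep.sensitivity - recall_score(y, p, zero_division=0)) < 1e-12
            assert abs(rep.f_score - f1_score(y, p, zero_division=0)) < 1e-12

    def test_macro_averaging_for_three_classes(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        preds = np.array([0, 1, 1, 1, 2, 0])
        rep = compute_metrics(labels, preds, K=3)
        # per-class recalls: 1/2, 2/2, 1/2 -> macro 2/3
        assert abs(rep.sensitivity - 2.0 / 3.0) < 1e-12
        assert rep.confusion.sum() == 6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(np.array([]), np.array([]), K=2)


class TestRocCurve:
    def test_perfect_ranking_has_auc_one(self):
        labels = np.array([0, 0, 1, 1])
        pts, auc = roc_curve(labels, labels.astype(float))
        assert auc == 1.0
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_constant_scores_are_chance(self):
        labels = np.array([0, 1, 0, 1])
        _, auc = roc_curve(labels, np.full(4, 0.5))
        assert abs(auc - 0.5) < 1e-12

    def test_four_point_toy_matches_pairwise_oracle(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        _, auc = roc_curve(labels, scores)
        assert abs(auc - 0.75) < 1e-12
        assert abs(auc - mann_whitney_auc(labels, scores)) < 1e-12

    def test_auc_equals_concordance_on_random_scores(self):
        rng = np.random.default_rng(1)
        for n in (20, 100, 200):
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)    # force ties
            _, auc = roc_curve(labels, scores)
            assert abs(auc - mann_whitney_auc(labels, scores)) < 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_curve(np.zeros(4, dtype=int), np.random.default_rng(0).random(4))

    def test_fpr_nondecreasing(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, size=60)
        labels[0], labels[1] = 0, 1
        pts, _ = roc_curve(labels, rng.random(60))
        fpr = np.array([p[0] for p in pts])
        assert np.all(np.diff(fpr) >= 0)


class TestGaussianNoise:
    def test_zero_std_is_identity(self, rng):
        batch = rng.random((3, 8, 8))
        out = add_gaussian_noise(batch, 0.0, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, batch)

    def test_std_close_to_nominal_on_midgray(self):
        batch = np.full((50, 32, 32), 0.5)
        out = add_gaussian_noise(batch, 0.0, 0.05, np.random.default_rng(3))
        assert abs((out - batch).std() - 0.05) < 0.005

    def test_clipping_keeps_unit_interval(self):
        batch = np.ones((10, 16, 16))
        out = add_gaussian_noise(batch, 0.0, 0.2, np.random.default_rng(4))
        assert out.max() <= 1.0 and out.min() >= 0.0

    def test_negative_std_rejected(self):
        with pytest.raises(ValueError, match="std"):
            add_gaussian_noise(np.zeros((1, 4, 4)), 0.0, -0.1,
                               np.random.default_rng(0))


@pytest.fixture(scope="module")
def quick_checkpoint():
    ds = generate_dataset(SyntheticSpec(
        n_subjects=8, images_per_subject=10, image_size=32,
        regime="local", seed=21))
    cfg = small_model_config("cnn_only")
    tc = fast_train_config(0, max_epochs=6)
    ckpt, _ = train_model(ds, cfg, tc)
    return ckpt, ds


class TestEvaluateConditions:
    def test_zero_noise_condition_equals_clean(self, quick_checkpoint):
        ckpt, ds = quick_checkpoint
        test = ds.subset(ckpt["splits"][2])
        reports = evaluate_conditions(ckpt, test, noise_std=0.0, seed=0)
        assert reports[0].accuracy == reports[1].accuracy
        assert reports[1].extras["accuracy_drop"] == 0.0

    def test_domain_shift_condition_is_reported(self, quick_checkpoint):
        ckpt, ds = quick_checkpoint
        test = ds.subset(ckpt["splits"][2])
        reports = evaluate_conditions(
            ckpt, test, noise_std=0.05,
            shift_params=DomainShiftParams(gamma=1.4, extra_noise_std=0.02), seed=0)
        assert [r.condition for r in reports] == ["clean", "noisy", "shifted"]
        for rep in reports:
            assert 0.0 <= rep.accuracy <= 1.0

    def test_untrained_model_sits_in_chance_band(self):
        from adsaf.model import init_params
        from adsaf.training import predict_proba, preprocess
        ds = generate_dataset(SyntheticSpec(
            n_subjects=20, images_per_subject=10, image_size=32,
            regime="local", seed=33))
        cfg = small_model_config("full_adsaf")
        params = init_params(cfg, 32, seed=17)
        probs, _ = predict_proba(params, preprocess(ds.images, 32), cfg)
        acc = float((probs.argmax(axis=1) == ds.labels).mean())
        # 99.9% binomial band around 0.5 at n=200
        assert abs(acc - 0.5) < 3.3 * np.sqrt(0.25 / len(ds))
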