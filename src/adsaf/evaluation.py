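"""Metrics and robustness protocols.

Binary metrics follow the clinical convention with class 1 as positive:
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), F-score = F1 (harmonic
mean of precision and recall).  For K > 2 classes, macro averages with
one-vs-rest specificity are reported.  A degenerate all-one-class predictor
on balanced binary data therefore scores specificity 0 (all-positive) or
sensitivity 0 (all-negative).

Robustness conditions mirror the evaluation protocol: additive Gaussian
noise (mean 0, std 0.05) on the test images, and a simulated domain shift
(gamma contrast warp + changed noise statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .config import DomainShiftParams, ModelConfig
from .synthetic import ImageDataset, apply_domain_shift
from .training import predict_proba, preprocess


@dataclass
class MetricsReport:
    condition: str                      # {"clean", "noisy", "shifted"}
    accuracy: float
    f_score: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray               # (K, K), rows = true class
    roc_points: Optional[list] = None   # [(fpr, tpr), ...]
    auc: Optional[float] = None
    mean_alpha: Optional[float] = None
    extras: dict = field(default_factory=dict)


def confusion_matrix(labels, predictions, K: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    cm = np.zeros((K, K), dtype=int)
    np.add.at(cm, (labels, predictions), 1)
    return cm


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else 0.0


def compute_metrics(labels, predictions, K: int = 2,
                    condition: str = "clean") -> MetricsReport:
    """Accuracy, F-score, sensitivity and specificity from hard predictions."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.size == 0:
        raise ValueError("cannot compute metrics on an empty input")
    if labels.shape != predictions.shape:
        raise ValueError(
            f"labels and predictions must have equal length, "
            f"got {labels.shape} vs {predictions.shape}")
    cm = confusion_matrix(labels, predictions, K)
    accuracy = float(np.trace(cm) / cm.sum())
    if K == 2:
        tn, fp = cm[0, 0], cm[0, 1]
        fn, tp = cm[1, 0], cm[1, 1]
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        prec = _safe_div(tp, tp + fp)
        f1 = _safe_div(2 * prec * sens, prec + sens)
    else:
        sens_k, spec_k, f1_k = [], [], []
        for k in range(K):
            tp = cm[k, k]
            fn = cm[k].sum() - tp
            fp = cm[:, k].sum() - tp
            tn = cm.sum() - tp - fn - fp
            s = _safe_div(tp, tp + fn)
            p = _safe_div(tp, tp + fp)
            sens_k.append(s)
            spec_k.append(_safe_div(tn, tn + fp))
            f1_k.append(_safe_div(2 * p * s, p + s))
        sens, spec, f1 = map(lambda v: float(np.mean(v)), (sens_k, spec_k, f1_k))
    return MetricsReport(condition=condition, accuracy=accuracy, f_score=float(f1),
                         sensitivity=float(sens), specificity=float(spec),
                         confusion=cm)


def roc_curve(labels, positive_scores) -> Tuple[list, float]:
    """ROC points (fpr, tpr) from (0,0) to (1,1) and the trapezoidal AUC."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(positive_scores, dtype=float)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("ROC needs both classes present in the labels")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts, float(_sk_auc(fpr, tpr))


def add_gaussian_noise(batch: np.ndarray, mean: float, std: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Additive i.i.d. Gaussian pixel noise, clipped back to [0, 1]."""
    if std < 0:
        raise ValueError(f"noise std must be >= 0, got {std}")
    if std == 0 and mean == 0:
        return batch.copy()
    return np.clip(batch + rng.normal(mean, std, size=batch.shape), 0.0, 1.0)


def evaluate_model(params, images: np.ndarray, labels: np.ndarray,
                   cfg: ModelConfig, condition: str = "clean") -> MetricsReport:
    """Full report (metrics + ROC/AUC for binary tasks) for one condition."""
    probs, alpha = predict_proba(params, images, cfg)
    preds = probs.argmax(axis=1)
    rep = compute_metrics(labels, preds, cfg.n_classes, condition=condition)
    if cfg.n_classes == 2 and np.unique(labels).size == 2:
        rep.roc_points, rep.auc = roc_curve(labels, probs[:, 1])
    if alpha is not None:
        rep.mean_alpha = float(np.mean(alpha))
    return rep


def evaluate_conditions(checkpoint: dict, test_set: ImageDataset,
                        noise_std: float = 0.05,
                        shift_params: Optional[DomainShiftParams] = None,
                        seed: int = 0) -> List[MetricsReport]:
    """Evaluate clean / noisy / (optionally) domain-shifted test conditions.

    Noise uses mean 0 and ``noise_std`` (default 0.05).  Each corrupted
    report's ``extras['accuracy_drop']`` is the clean-minus-corrupted gap.
    """
    params, cfg = checkpoint["params"], checkpoint["model_cfg"]
    size = checkpoint["train_cfg"].image_size
    x = preprocess(test_set.images, size)
    y = np.asarray(test_set.labels, dtype=int)

    reports = [evaluate_model(params, x, y, cfg, condition="clean")]
    rng = np.random.default_rng(seed)
    x_noisy = add_gaussian_noise(x, 0.0, noise_std, rng)
    noisy = evaluate_model(params, x_noisy, y, cfg, condition="noisy")
    noisy.extras["accuracy_drop"] = reports[0].accuracy - noisy.accuracy
    reports.append(noisy)
    if shift_params is not None:
        shifted_ds = apply_domain_shift(test_set, shift_params, seed=seed + 1)
        xs = preprocess(shifted_ds.images, size)
        shifted = evaluate_model(params, xs, y, cfg, condition="shifted")
        shifted.extras["accuracy_drop"] = reports[0].accuracy - shifted.accuracy
        reports.append(shifted)
    return reports
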