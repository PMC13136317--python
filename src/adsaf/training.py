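"""Training pipeline: preprocessing, subject-wise splits, augmentation,
Adam optimization with plateau LR decay and accuracy-based early stopping.

Protocol defaults: batch 32, Adam at 1e-3, LR x0.1 after a 5-epoch
validation-loss plateau, up to 50 epochs, early stop after 7 epochs without
validation-accuracy improvement, 70/20/10 subject-wise splits, and
flip/rotate/zoom/shift augmentation each applied with probability 0.5.
Two runs with identical config and seed produce identical histories.
"""

from __future__ import annotations

import json
import os
from typing import Tuple

import numpy as np
import pandas as pd
from autograd import value_and_grad
from autograd.misc import flatten
from scipy import ndimage

from .config import AugmentConfig, ModelConfig, TrainConfig, config_to_dict, experiment_from_dict
from .model import batch_loss, forward, init_params, objective
from .ops import bilinear_resize
from .synthetic import ImageDataset

PLATEAU_MIN_DELTA = 1e-4


# ---------------------------------------------------------------------------
# preprocessing & augmentation


def preprocess(images: np.ndarray, image_size: int) -> np.ndarray:
    """Scale intensities to [0, 1] and bilinearly resize to a square grid.

    Accepts ``(N, H, W)`` float arrays (already in [0, 1]) or integer arrays
    in {0..255}, which are divided by 255 exactly.
    """
    x = np.asarray(images)
    if x.ndim != 3:
        raise ValueError(f"expected (N, H, W) images, got shape {x.shape}")
    if np.issubdtype(x.dtype, np.integer):
        x = x.astype(float) / 255.0
    else:
        x = x.astype(float)
    if x.shape[1:] != (image_size, image_size):
        x = bilinear_resize(x[:, None, :, :], image_size, image_size)[:, 0]
    return x


def split_subjectwise(dataset: ImageDataset, proportions, seed: int
                      ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition *subjects* (never images) into train/val/test index sets.

    Subjects are shuffled with ``seed`` and allotted by rounded proportions;
    every split with a nonzero proportion receives at least one subject.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {proportions}")
    subjects = list(dict.fromkeys(dataset.subject_ids))   # stable unique order
    S = len(subjects)
    n_needed = sum(1 for p in proportions if p > 0)
    if S < max(3, n_needed):
        raise ValueError(f"need at least 3 subjects for a 3-way split, got {S}")
    order = np.random.default_rng(seed).permutation(S)
    counts = [int(np.floor(p * S)) for p in proportions]
    rema = [p * S - c for p, c in zip(proportions, counts)]
    while sum(counts) < S:
        i = int(np.argmax(rema))
        counts[i] += 1
        rema[i] = -1
    for i, p in enumerate(proportions):
        if p > 0 and counts[i] == 0:
            counts[int(np.argmax(counts))] -= 1
            counts[i] = 1
    bounds = np.cumsum([0] + counts)
    sets = []
    sid = np.asarray(dataset.subject_ids)
    for k in range(3):
        chosen = {subjects[j] for j in order[bounds[k]:bounds[k + 1]]}
        sets.append(np.flatnonzero(np.isin(sid, list(chosen))))
    return tuple(sets)


def _augment_one(im: np.ndarray, aug: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    size = im.shape[0]
    if aug.hflip and rng.random() < 0.5:
        im = im[:, ::-1]
    if aug.rotate_deg > 0 and rng.random() < 0.5:
        angle = rng.uniform(-aug.rotate_deg, aug.rotate_deg)
        im = ndimage.rotate(im, angle, reshape=False, order=1, mode="nearest")
    if aug.zoom_range > 0 and rng.random() < 0.5:
        z = rng.uniform(1.0 - aug.zoom_range, 1.0 + aug.zoom_range)
        c = (size - 1) / 2.0
        im = ndimage.affine_transform(
            im, np.diag([1.0 / z, 1.0 / z]),
            offset=[c - c / z, c - c / z], order=1, mode="nearest")
    if aug.shift_range > 0 and rng.random() < 0.5:
        dy = rng.uniform(-aug.shift_range, aug.shift_range) * size
        dx = rng.uniform(-aug.shift_range, aug.shift_range) * size
        im = ndimage.shift(im, (dy, dx), order=1, mode="nearest")
    return np.clip(im, 0.0, 1.0)


def augment_batch(batch: np.ndarray, aug: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply stochastic flip/rotate/zoom/shift to each image independently."""
    return np.stack([_augment_one(np.ascontiguousarray(im), aug, rng) for im in batch])


# ---------------------------------------------------------------------------
# optimizer & schedules


class Adam:
    """Plain Adam over a flattened parameter pytree."""

    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        flat, self.unflatten = flatten(params)
        self.x = flat.astype(float)
        self.m = np.zeros_like(self.x)
        self.v = np.zeros_like(self.x)
        self.t = 0
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps

    @property
    def params(self):
        return self.unflatten(self.x)

    def step(self, grads) -> None:
        g, _ = flatten(grads)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        self.x = self.x - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PlateauScheduler:
    """Multiply the LR by ``factor`` when the monitored loss stops improving.

    'No improvement' means no decrease beyond ``min_delta``.  The counter
    resets after each reduction.
    """

    def __init__(self, lr: float, factor: float, patience: int,
                 min_delta: float = PLATEAU_MIN_DELTA):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.counter = 0

    def step(self, loss: float) -> float:
        if loss < self.best - self.min_delta:
            self.best = loss
            self.counter = 0
        else:
            self.counter += 1
            if self.counter >= self.patience:
                self.lr *= self.factor
                self.counter = 0
        return self.lr


class EarlyStopper:
    """Stop when the monitored accuracy fails to improve for ``patience`` epochs."""

    def __init__(self, patience: int, min_delta: float = PLATEAU_MIN_DELTA):
        self.patience = patience
        self.min_delta = min_delta
        self.best = -np.inf
        self.counter = 0

    def step(self, acc: float) -> bool:
        if acc > self.best + self.min_delta:
            self.best = acc
            self.counter = 0
        else:
            self.counter += 1
        return self.counter >= self.patience


# ---------------------------------------------------------------------------
# evaluation helpers


def predict_proba(params, images: np.ndarray, cfg: ModelConfig,
                  batch_size: int = 64):
    """Class probabilities and gate weights over a dataset, in batches."""
    probs, alphas = [], []
    for i in range(0, len(images), batch_size):
        pred = forward(params, images[i:i + batch_size], cfg)
        probs.append(pred.probabilities)
        if pred.alpha is not None:
            alphas.append(pred.alpha)
    probs = np.concatenate(probs)
    alpha = np.concatenate(alphas) if alphas else None
    return probs, alpha


def _eval_split(params, images, labels, cfg: ModelConfig, batch_size: int):
    total, ce, n = 0.0, 0.0, 0
    probs_all, alphas = [], []
    for i in range(0, len(images), batch_size):
        xb, yb = images[i:i + batch_size], labels[i:i + batch_size]
        loss, parts = batch_loss(params, xb, yb, cfg)
        w = len(yb)
        total += float(loss) * w
        ce += float(parts["ce"]) * w
        n += w
        pred = forward(params, xb, cfg)
        probs_all.append(pred.probabilities)
        if parts["alpha"] is not None:
            alphas.append(np.asarray(parts["alpha"]))
    probs = np.concatenate(probs_all)
    acc = float((probs.argmax(axis=1) == labels).mean())
    alpha = np.concatenate(alphas) if alphas else None
    return {"loss": total / n, "ce": ce / n, "accuracy": acc, "alpha": alpha}


# ---------------------------------------------------------------------------
# main loop


def train_model(dataset: ImageDataset, model_cfg: ModelConfig,
                train_cfg: TrainConfig, splits=None, verbose: bool = False):
    """Train one variant; returns ``(checkpoint, history)``.

    ``checkpoint`` holds the best-validation-accuracy parameters plus both
    configs and the split indices; ``history`` is a per-epoch DataFrame with
    losses, accuracies, the LR, and the mean gate weight / fusion entropy.
    """
    from .fusion import fusion_entropy  # local import to avoid cycle at module load

    model_cfg.validate()
    train_cfg.validate()
    if splits is None:
        splits = split_subjectwise(dataset, train_cfg.split, train_cfg.seed)
    train_idx, val_idx, _ = splits
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("train and validation splits must be non-empty")

    x_all = preprocess(dataset.images, train_cfg.image_size)
    y_all = np.asarray(dataset.labels, dtype=int)
    x_tr, y_tr = x_all[train_idx], y_all[train_idx]
    x_va, y_va = x_all[val_idx], y_all[val_idx]

    params = init_params(model_cfg, train_cfg.image_size, seed=train_cfg.seed)
    opt = Adam(params, lr=train_cfg.lr)
    sched = PlateauScheduler(train_cfg.lr, train_cfg.lr_factor, train_cfg.lr_patience)
    stopper = EarlyStopper(train_cfg.early_stop_patience)
    shuffle_rng = np.random.default_rng(train_cfg.seed + 1_000_003)
    aug_rng = np.random.default_rng(train_cfg.seed + 2_000_003)
    grad_fn = value_and_grad(objective)

    best_acc, best_flat, best_epoch = -np.inf, opt.x.copy(), 0
    rows = []
    for epoch in range(1, train_cfg.max_epochs + 1):
        order = shuffle_rng.permutation(len(x_tr))
        epoch_loss, nseen = 0.0, 0
        for i in range(0, len(order), train_cfg.batch_size):
            idx = order[i:i + train_cfg.batch_size]
            xb = augment_batch(x_tr[idx], train_cfg.augment, aug_rng)
            loss, grads = grad_fn(opt.params, xb, y_tr[idx], model_cfg)
            opt.lr = sched.lr
            opt.step(grads)
            epoch_loss += float(loss) * len(idx)
            nseen += len(idx)
        train_stats = _eval_split(opt.params, x_tr, y_tr, model_cfg, train_cfg.batch_size)
        val_stats = _eval_split(opt.params, x_va, y_va, model_cfg, train_cfg.batch_size)
        lr_now = sched.step(val_stats["loss"])
        alpha = val_stats["alpha"]
        rows.append({
            "epoch": epoch,
            "train_loss": epoch_loss / nseen,
            "train_accuracy": train_stats["accuracy"],
            "val_loss": val_stats["loss"],
            "val_accuracy": val_stats["accuracy"],
            "lr": lr_now,
            "mean_alpha": np.nan if alpha is None else float(np.mean(alpha)),
            "mean_entropy": np.nan if alpha is None else float(fusion_entropy(alpha)),
        })
        if verbose:
            r = rows[-1]
            print(f"epoch {epoch:3d}  val_loss {r['val_loss']:.4f}  "
                  f"val_acc {r['val_accuracy']:.3f}  lr {r['lr']:.2e}")
        if val_stats["accuracy"] > best_acc:
            best_acc = val_stats["accuracy"]
            best_flat = opt.x.copy()
            best_epoch = epoch
        if stopper.step(val_stats["accuracy"]):
            break

    history = pd.DataFrame(rows)
    checkpoint = {
        "params": opt.unflatten(best_flat),
        "final_params": opt.params,
        "model_cfg": model_cfg,
        "train_cfg": train_cfg,
        "epoch": best_epoch,
        "val_accuracy": float(best_acc),
        "splits": splits,
    }
    return checkpoint, history


# ---------------------------------------------------------------------------
# checkpoint persistence


def save_checkpoint(checkpoint: dict, path_prefix: str) -> None:
    """Write ``<prefix>.npz`` (flat parameters) + ``<prefix>.json`` manifest."""
    os.makedirs(os.path.dirname(path_prefix) or ".", exist_ok=True)
    flat, _ = flatten(checkpoint["params"])
    np.savez(path_prefix + ".npz", flat=flat)
    from .config import config_hash
    manifest = {
        "model_cfg": config_to_dict(checkpoint["model_cfg"]),
        "train_cfg": config_to_dict(checkpoint["train_cfg"]),
        "epoch": checkpoint["epoch"],
        "val_accuracy": checkpoint["val_accuracy"],
        "config_hash": config_hash(checkpoint["model_cfg"]),
        "seed": checkpoint["train_cfg"].seed,
    }
    with open(path_prefix + ".json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_checkpoint(path_prefix: str):
    """Rebuild a checkpoint saved by :func:`save_checkpoint`."""
    if not os.path.exists(path_prefix + ".npz"):
        raise FileNotFoundError(f"checkpoint not found: {path_prefix}.npz")
    with open(path_prefix + ".json") as fh:
        manifest = json.load(fh)
    exp = experiment_from_dict({"model": manifest["model_cfg"],
                                "train": manifest["train_cfg"],
                                "data_dir": "unused"})
    model_cfg, train_cfg = exp.model, exp.train
    skeleton = init_params(model_cfg, train_cfg.image_size, seed=train_cfg.seed)
    _, unflat = flatten(skeleton)
    flat = np.load(path_prefix + ".npz")["flat"]
    return {
        "params": unflat(flat),
        "model_cfg": model_cfg,
        "train_cfg": train_cfg,
        "epoch": manifest["epoch"],
        "val_accuracy": manifest["val_accuracy"],
        "splits": None,
    }
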