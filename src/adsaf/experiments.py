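"""Reusable seeded experiments on the synthetic local/global benchmark.

These runners define the package's standard desk-scale study conditions —
32 px images, a compact dual-stream model, and datasets of a few hundred
images — and are shared by the test suite and by reproduction scripts so
that both measure exactly the same quantities:

* **dominance recovery** — after training on local-regime data the mean
  gate weight should favor the CNN stream (alpha high); on global-regime
  data the ViT stream (alpha low);
* **entropy pressure** — an identically seeded run with lambda > 0 ends
  with lower mean binary gate entropy than its lambda = 0 twin;
* **learning sanity** — the full model reaches high validation accuracy on
  the mixed-regime task;
* **ablation ordering** — full model vs gate-only vs static concatenation
  on one mixed-regime task, with noise-robustness drops from the same
  checkpoints.
"""

from __future__ import annotations

import numpy as np

from .config import AugmentConfig, ModelConfig, StreamConfig, SyntheticSpec, TrainConfig
from .evaluation import evaluate_conditions
from .fusion import fusion_entropy
from .synthetic import generate_dataset
from .training import predict_proba, preprocess, split_subjectwise, train_model

IMAGE_SIZE = 32


def small_stream_config() -> StreamConfig:
    """Compact dual-stream architecture for 32 px experiments."""
    return StreamConfig(
        common_channels=32,
        cnn_blocks=((16, 2), (32, 2), (32, 2)),
        patch_size=8,
        embed_dim=32,
        n_heads=2,
        n_layers=2,
        mlp_ratio=2.0,
    )


def small_model_config(variant: str = "full_adsaf",
                       lambda_entropy: float = 0.1) -> ModelConfig:
    if variant not in ("adaptive_no_sarm", "full_adsaf"):
        lambda_entropy = 0.0
    return ModelConfig(variant=variant, lambda_entropy=lambda_entropy,
                       stream=small_stream_config(), sarm_kernel=3)


def regime_spec(regime: str, seed: int, n_subjects: int = 24,
                images_per_subject: int = 10) -> SyntheticSpec:
    return SyntheticSpec(n_subjects=n_subjects, images_per_subject=images_per_subject,
                         image_size=IMAGE_SIZE, regime=regime, seed=seed)


def fast_train_config(seed: int, max_epochs: int = 15) -> TrainConfig:
    """Training protocol for the synthetic tasks.

    Keeps the optimizer/scheduler/early-stop protocol but disables
    augmentation: the global-regime layout is a diagonal quadrant pattern,
    which horizontal flips and rotations would map onto the *opposite*
    class, corrupting the labels.
    """
    return TrainConfig(
        batch_size=32, lr=1e-3, lr_factor=0.1, lr_patience=5,
        early_stop_patience=7, max_epochs=max_epochs,
        augment=AugmentConfig(hflip=False, rotate_deg=0.0,
                              zoom_range=0.0, shift_range=0.0),
        image_size=IMAGE_SIZE, seed=seed,
    )


def train_on_regime(regime: str, variant: str, seed: int, *,
                    lambda_entropy: float = 0.1, n_subjects: int = 24,
                    images_per_subject: int = 10, max_epochs: int = 15):
    """Generate a regime dataset and train one variant on it.

    Returns ``(checkpoint, history, dataset)``; the checkpoint carries the
    subject-wise splits used.
    """
    ds = generate_dataset(regime_spec(regime, seed, n_subjects, images_per_subject))
    cfg = small_model_config(variant, lambda_entropy)
    ckpt, hist = train_model(ds, cfg, fast_train_config(seed, max_epochs))
    return ckpt, hist, ds


def mean_alpha_on_split(ckpt: dict, dataset, split: str = "val",
                        final: bool = True) -> float:
    """Mean gate weight of a trained model over one of its splits.

    ``final=True`` uses the end-of-training parameters (the converged gate
    state, which is what the dominance property is about); ``final=False``
    uses the best-validation-accuracy snapshot.
    """
    idx = {"train": 0, "val": 1, "test": 2}[split]
    sel = ckpt["splits"][idx]
    x = preprocess(dataset.images[sel], ckpt["train_cfg"].image_size)
    params = ckpt["final_params"] if final and "final_params" in ckpt else ckpt["params"]
    _, alpha = predict_proba(params, x, ckpt["model_cfg"])
    return float(np.mean(alpha))


def dominance_experiment(seeds=(0, 1, 2), max_epochs: int = 15) -> dict:
    """Train the full model on local and on global regime data per seed.

    Returns per-seed mean validation-gate weights and the across-seed means.
    """
    out = {"local": [], "global": []}
    for regime in ("local", "global"):
        for seed in seeds:
            ckpt, _, ds = train_on_regime(regime, "full_adsaf", seed,
                                          max_epochs=max_epochs)
            out[regime].append(mean_alpha_on_split(ckpt, ds, "val"))
    out["local_mean"] = float(np.mean(out["local"]))
    out["global_mean"] = float(np.mean(out["global"]))
    return out


def entropy_pressure_experiment(seed: int = 0, lam: float = 0.5,
                                max_epochs: int = 30) -> dict:
    """Identically seeded twin runs on mixed-regime data, lambda vs 0.

    Uses the 600-image mixed task (the gate needs past the initial
    accuracy plateau to move at all) and compares the *final* mean binary
    gate entropies of the two runs.
    """
    ds = generate_dataset(regime_spec("mixed", seed, n_subjects=30,
                                      images_per_subject=20))
    res = {}
    for key, l in (("lambda_pos", lam), ("lambda_zero", 0.0)):
        cfg = small_model_config("full_adsaf", l)
        ckpt, hist = train_model(ds, cfg, fast_train_config(seed, max_epochs))
        x = preprocess(ds.images[ckpt["splits"][1]], IMAGE_SIZE)
        _, alpha = predict_proba(ckpt["final_params"], x, ckpt["model_cfg"])
        res[key] = float(fusion_entropy(alpha))
    return res


def sanity_experiment(seed: int = 0, max_epochs: int = 30) -> dict:
    """Full model on 600 mixed-regime images; best validation accuracy."""
    ckpt, hist, _ = train_on_regime("mixed", "full_adsaf", seed,
                                    n_subjects=30, images_per_subject=20,
                                    max_epochs=max_epochs)
    return {"best_val_accuracy": ckpt["val_accuracy"],
            "epochs_run": int(hist["epoch"].max()),
            "history": hist}


def ablation_experiment(seeds=(0, 1, 2), max_epochs: int = 25,
                        noise_std: float = 0.05,
                        lambda_entropy: float = 0.01) -> dict:
    """Train fusion-ablation variants on identical seeded mixed tasks.

    For each seed the three dual-stream variants (static_concat,
    adaptive_no_sarm, full_adsaf) share the same dataset and splits.  The
    same checkpoints are evaluated clean and under Gaussian test noise, so
    the robustness comparison is paired.  Returns per-variant mean
    validation accuracy, mean clean/noisy test accuracy, and the drops.

    The mixed task contains *both* signal regimes, so each gated model must
    keep both streams alive long enough to learn both subtasks before the
    gate commits per image; the entropy weight is accordingly mild here
    (strong pressure causes premature single-stream collapse — the
    underfitting risk that motivates controlling lambda empirically).
    """
    variants = ("static_concat", "adaptive_no_sarm", "full_adsaf")
    acc = {v: [] for v in variants}
    clean = {v: [] for v in variants}
    noisy = {v: [] for v in variants}
    for seed in seeds:
        ds = generate_dataset(regime_spec("mixed", seed, n_subjects=30,
                                          images_per_subject=20))
        tc = fast_train_config(seed, max_epochs)
        splits = split_subjectwise(ds, tc.split, tc.seed)
        for v in variants:
            cfg = small_model_config(v, lambda_entropy)
            ckpt, _ = train_model(ds, cfg, tc, splits=splits)
            acc[v].append(ckpt["val_accuracy"])
            test = ds.subset(splits[2])
            reports = evaluate_conditions(ckpt, test, noise_std=noise_std,
                                          seed=seed)
            clean[v].append(reports[0].accuracy)
            noisy[v].append(reports[1].accuracy)
    out = {}
    for v in variants:
        out[v] = {
            "val_accuracy": float(np.mean(acc[v])),
            "clean_accuracy": float(np.mean(clean[v])),
            "noisy_accuracy": float(np.mean(noisy[v])),
            "noise_drop": float(np.mean(clean[v]) - np.mean(noisy[v])),
            "per_seed_val": [float(a) for a in acc[v]],
        }
    return out
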