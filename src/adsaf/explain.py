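"""Grad-CAM heatmaps for the CNN branch, the ViT branch and the fused map.

For a chosen branch feature grid ``F`` (cnn: last conv map; vit: aligned
token grid; fused: the refined map) and target class ``c``, the heatmap is

    H = ReLU( sum_k w_k F_k ),   w_k = spatial mean of d logit_c / d F_k,

upsampled bilinearly to the input size and min-max normalized to [0, 1]
(an exactly constant raw map yields all zeros).  Gradients are taken with
the *other* stream's features held fixed, so the cnn/vit heatmaps isolate
each branch's contribution through the gate, fusion and refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from autograd import grad

from .model import forward_from_features, stream_features
from .ops import bilinear_resize
from .streams import FeatureMap

BRANCHES = ("cnn", "vit", "fused")


@dataclass
class Heatmap:
    values: np.ndarray     # (H, W) in [0, 1]
    branch: str
    target_class: int


def _branch_error(branch: str, variant: str) -> ValueError:
    return ValueError(
        f"branch {branch!r} is not available on variant {variant!r}")


def grad_cam(checkpoint: dict, image: np.ndarray, target_class: int,
             branch: str = "fused") -> Heatmap:
    """Gradient-weighted class activation map for one image.

    ``image`` is ``(H, W)`` in [0, 1] at the model's input size.
    """
    if branch not in BRANCHES:
        raise ValueError(f"branch must be one of {BRANCHES}, got {branch!r}")
    params, cfg = checkpoint["params"], checkpoint["model_cfg"]
    variant = cfg.variant
    if branch == "cnn" and variant == "vit_only":
        raise _branch_error(branch, variant)
    if branch == "vit" and variant == "cnn_only":
        raise _branch_error(branch, variant)
    if branch == "fused" and variant in ("cnn_only", "vit_only"):
        raise _branch_error(branch, variant)

    x = np.asarray(image, dtype=float)[None]
    H, W = x.shape[1:]
    f_cnn, f_vit = stream_features(params, x, cfg)

    if branch == "fused":
        # differentiate w.r.t. the map entering the head (refined for full)
        def logit_of(v):
            from .model import head_logits
            return head_logits(params, FeatureMap(v, "refined"))[0, target_class]

        inner = forward_from_features(params, f_cnn, f_vit, cfg)
        feat = inner["final_map"].values
    else:
        held = {"cnn": f_vit, "vit": f_cnn}[branch]

        def logit_of(v):
            injected = FeatureMap(v, branch)
            if branch == "cnn":
                out = forward_from_features(params, injected, held, cfg)
            else:
                out = forward_from_features(params, held, injected, cfg)
            return out["logits"][0, target_class]

        feat = (f_cnn if branch == "cnn" else f_vit).values

    if not 0 <= target_class < params["head"]["W"].shape[1]:
        raise ValueError(f"target_class {target_class} out of range")
    g = grad(logit_of)(feat)                      # (1, C, h, w)
    weights = np.mean(np.asarray(g), axis=(2, 3))  # (1, C)
    cam = np.maximum((weights[:, :, None, None] * np.asarray(feat)).sum(axis=1), 0.0)
    cam = np.asarray(bilinear_resize(cam[:, None], H, W))[0, 0]
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return Heatmap(values=np.zeros((H, W)), branch=branch,
                       target_class=int(target_class))
    return Heatmap(values=(cam - lo) / (hi - lo), branch=branch,
                   target_class=int(target_class))


def overlay_png(image: np.ndarray, heatmap: Heatmap, path: str) -> None:
    """Blend the heatmap (red channel) over the grayscale input and save."""
    from PIL import Image

    base = np.clip(image, 0, 1)
    h = heatmap.values
    rgb = np.stack([np.clip(0.5 * base + 0.5 * h, 0, 1),
                    0.5 * base, 0.5 * base], axis=-1)
    Image.fromarray(np.round(rgb * 255).astype(np.uint8), mode="RGB").save(path)
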