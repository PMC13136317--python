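"""Full network assembly: streams -> adaptive fusion -> SARM -> head.

Five variants are supported, mirroring the ablation axis of the design:

* ``cnn_only`` / ``vit_only`` — a single stream, pooled straight into the head;
* ``static_concat`` — channel-concatenation of the aligned maps with a 1x1
  projection back to C (the fixed-fusion baseline);
* ``adaptive_no_sarm`` — entropy-regularized gate + convex fusion, no
  refinement;
* ``full_adsaf`` — gate + fusion + self-attention refinement.

The joint objective is ``L_total = L_CE + lambda * L_fusion`` where
``L_fusion`` is the batch-mean binary entropy of the gate weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import autograd.numpy as anp
import numpy as np

from .config import GATED_VARIANTS, ModelConfig
from .fusion import FusionGateOutput, compute_gate, fuse, fusion_entropy, init_gate_params
from .ops import as_array, global_avg_pool, linear, log_softmax, rms_normalize, softmax, xavier_init
from .refinement import init_sarm_params, sarm_apply
from .streams import (
    FeatureMap,
    align_vit_to_map,
    cnn_forward,
    init_align_params,
    init_cnn_params,
    init_vit_params,
    patch_embed,
    vit_forward,
)

CE_EPS = 1e-12


@dataclass
class Prediction:
    probabilities: anp.ndarray          # (N, K)
    logits: anp.ndarray                 # (N, K)
    alpha: Optional[anp.ndarray] = None  # (N,) for gated variants
    loss_terms: dict = field(default_factory=dict)


def _needs_cnn(variant: str) -> bool:
    return variant != "vit_only"


def _needs_vit(variant: str) -> bool:
    return variant != "cnn_only"


def feature_grid_shape(cfg: ModelConfig, image_size: int) -> tuple[int, int]:
    """Spatial size of the common feature grid for a given input size."""
    if cfg.variant == "vit_only":
        g = image_size // cfg.stream.patch_size
        return (g, g)
    f = cfg.stream.downsample_factor
    return (image_size // f, image_size // f)


def init_params(cfg: ModelConfig, image_size: int, seed: int, in_channels: int = 1) -> dict:
    """Build the full parameter pytree for a variant, deterministically."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    C = cfg.stream.common_channels
    params: dict = {}
    if _needs_cnn(cfg.variant):
        params["cnn"] = init_cnn_params(cfg.stream, rng, in_channels)
    if _needs_vit(cfg.variant):
        params["vit"] = init_vit_params(cfg.stream, image_size, rng, in_channels)
        params["align"] = init_align_params(cfg.stream, rng)
    if cfg.variant in GATED_VARIANTS:
        params["gate"] = init_gate_params(C, cfg.gate_hidden_width, rng)
    if cfg.variant == "static_concat":
        params["static_proj"] = {
            "W": xavier_init(rng, (2 * C, C), 2 * C, C),
            "b": np.zeros(C),
        }
    if cfg.variant == "full_adsaf":
        params["sarm"] = init_sarm_params(C, cfg.sarm_reduction, cfg.sarm_kernel, rng)
    params["head"] = {
        "W": xavier_init(rng, (C, cfg.n_classes), C, cfg.n_classes),
        "b": np.zeros(cfg.n_classes),
    }
    return params


def stream_features(params, x, cfg: ModelConfig):
    """Run whichever streams the variant needs; returns (f_cnn, f_vit).

    The final alignment step puts both maps on a common per-sample RMS
    activation scale, so the fusion gate arbitrates between feature
    *content* rather than raw stream amplitudes.
    """
    f_cnn = f_vit = None
    if _needs_cnn(cfg.variant):
        f_cnn = cnn_forward(x, params["cnn"], cfg.stream)
        f_cnn = FeatureMap(values=rms_normalize(f_cnn.values), stream_origin="cnn")
    if _needs_vit(cfg.variant):
        tokens = vit_forward(patch_embed(x, params["vit"], cfg.stream),
                             params["vit"], cfg.stream)
        if f_cnn is not None:
            target = f_cnn.values.shape[2:]
        else:
            target = tokens.grid_shape
        f_vit = align_vit_to_map(tokens, params["align"], target,
                                 cfg.stream.common_channels)
        f_vit = FeatureMap(values=rms_normalize(f_vit.values), stream_origin="vit")
    return f_cnn, f_vit


def head_logits(params, fmap: FeatureMap):
    return linear(global_avg_pool(fmap.values), params["head"]["W"], params["head"]["b"])


def forward_from_features(params, f_cnn, f_vit, cfg: ModelConfig, *,
                          force_alpha=None, skip_sarm: bool = False) -> dict:
    """Fusion + refinement + head on precomputed stream features.

    Split out so that explainability code can differentiate the class logit
    with respect to an injected branch feature map.
    """
    variant = cfg.variant
    gate_out = None
    if variant == "cnn_only":
        final = f_cnn
    elif variant == "vit_only":
        final = f_vit
    elif variant == "static_concat":
        cat = anp.concatenate([f_cnn.values, f_vit.values], axis=1)  # N, 2C, h, w
        p = params["static_proj"]
        proj = anp.einsum("nchw,ck->nkhw", cat, p["W"]) + p["b"][None, :, None, None]
        final = FeatureMap(values=proj, stream_origin="fused")
    else:
        if force_alpha is not None:
            n = f_cnn.values.shape[0]
            alpha = anp.full(n, float(force_alpha))
            gate_out = FusionGateOutput(alpha=alpha, batch_entropy=fusion_entropy(alpha))
        else:
            gate_out = compute_gate(f_cnn, f_vit, params["gate"])
        final = fuse(f_cnn, f_vit, gate_out.alpha)
        if variant == "full_adsaf" and not skip_sarm:
            final, maps = sarm_apply(final, params["sarm"])
        else:
            maps = None
    logits = head_logits(params, final)
    out = {"logits": logits, "final_map": final, "gate": gate_out}
    if variant == "full_adsaf":
        out["attention_maps"] = None if skip_sarm else maps
    return out


def forward(params, x, cfg: ModelConfig, *, force_alpha=None,
            skip_sarm: bool = False, return_intermediates: bool = False):
    """Full forward pass; returns a :class:`Prediction`.

    ``force_alpha`` overrides the learned gate (testing/analysis only);
    ``skip_sarm`` bypasses refinement on the full variant.
    """
    f_cnn, f_vit = stream_features(params, x, cfg)
    inner = forward_from_features(params, f_cnn, f_vit, cfg,
                                  force_alpha=force_alpha, skip_sarm=skip_sarm)
    logits = inner["logits"]
    gate = inner["gate"]
    pred = Prediction(
        probabilities=softmax(logits),
        logits=logits,
        alpha=None if gate is None else gate.alpha,
    )
    if return_intermediates:
        pred.loss_terms["intermediates"] = {
            "f_cnn": f_cnn, "f_vit": f_vit,
            "final_map": inner["final_map"],
            "attention_maps": inner.get("attention_maps"),
            "gate": gate,
        }
    return pred


# ---------------------------------------------------------------------------
# losses


def cross_entropy(probabilities, label):
    """Categorical cross-entropy ``-sum_k y_k ln p_k`` with one-hot targets.

    Accepts a single ``(K,)`` vector with an integer label, or an ``(N, K)``
    batch with ``(N,)`` labels (then the batch mean is returned).
    """
    p = as_array(probabilities)
    if p.ndim == 1:
        K = p.shape[0]
        if not 0 <= int(label) < K:
            raise ValueError(f"label {label} out of range for {K} classes")
        return -anp.log(anp.clip(p[int(label)], CE_EPS, 1.0))
    labels = np.asarray(label, dtype=int)
    K = p.shape[1]
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError(f"labels out of range for {K} classes")
    picked = p[anp.arange(p.shape[0]), labels]
    return -anp.mean(anp.log(anp.clip(picked, CE_EPS, 1.0)))


def total_loss(ce, fusion_term, lam: float):
    """Joint objective ``L_CE + lambda * L_fusion``."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return ce + lam * fusion_term


def batch_loss(params, x, y, cfg: ModelConfig):
    """Differentiable training objective on one batch.

    Returns ``(total, parts)`` where ``parts`` carries the cross-entropy,
    the fusion entropy and the mean gate weight as plain quantities.
    """
    f_cnn, f_vit = stream_features(params, x, cfg)
    inner = forward_from_features(params, f_cnn, f_vit, cfg)
    logits = inner["logits"]
    labels = np.asarray(y, dtype=int)
    logp = log_softmax(logits)
    ce = -anp.mean(logp[anp.arange(logits.shape[0]), labels])
    gate = inner["gate"]
    if gate is not None:
        lfus = gate.batch_entropy
        total = total_loss(ce, lfus, cfg.lambda_entropy)
        alpha = gate.alpha
    else:
        lfus = 0.0
        total = ce
        alpha = None
    return total, {"ce": ce, "fusion": lfus, "alpha": alpha}


def objective(params, x, y, cfg: ModelConfig):
    """Scalar objective for autograd."""
    return batch_loss(params, x, y, cfg)[0]
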