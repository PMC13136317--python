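"""Self-Attention Refinement Module (SARM).

Channel attention (squeeze-excitation style: global pool -> C/r bottleneck
-> sigmoid) and spatial attention (channel-wise mean & max maps -> k x k
conv -> sigmoid) multiplicatively modulate the fused feature grid:
``F_ref = A_c (x) A_s (x) F_fusion``.  Both maps are sub-unit multipliers,
so refinement can only attenuate, concentrating mass on informative
channels and regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .ops import ShapeError, conv2d, global_avg_pool, he_init, linear, relu, sigmoid, xavier_init
from .streams import FeatureMap


@dataclass
class AttentionMaps:
    channel_map: anp.ndarray   # (N, C) in [0, 1]
    spatial_map: anp.ndarray   # (N, h, w) in [0, 1]


def init_sarm_params(C: int, reduction: int, kernel: int, rng: np.random.Generator):
    if C % reduction != 0:
        raise ShapeError(f"channels {C} not divisible by reduction {reduction}")
    if kernel % 2 != 1:
        raise ShapeError(f"spatial attention kernel must be odd, got {kernel}")
    hidden = C // reduction
    # attention biases start positive so refinement opens near identity
    # (sigmoid(2) ~ 0.88): the module learns to *suppress*, rather than
    # having to learn to pass signal through at all
    return {
        "ch": {
            "W1": he_init(rng, (C, hidden), C), "b1": np.zeros(hidden),
            "W2": xavier_init(rng, (hidden, C), hidden, C), "b2": np.full(C, 2.0),
        },
        "sp": {
            "W": xavier_init(rng, (1, 2, kernel, kernel), 2 * kernel * kernel, 1),
            "b": np.full(1, 2.0),
        },
    }


def channel_attention(f: FeatureMap, params) -> anp.ndarray:
    """Per-sample channel weights: pool -> C/r bottleneck MLP -> sigmoid."""
    pooled = global_avg_pool(f.values)                       # N, C
    h = relu(linear(pooled, params["W1"], params["b1"]))
    return sigmoid(linear(h, params["W2"], params["b2"]))    # N, C


def spatial_attention(f: FeatureMap, params) -> anp.ndarray:
    """Per-sample spatial grid: [mean; max] over channels -> conv -> sigmoid.

    The conv uses reflective padding so a spatially constant input yields a
    spatially constant attention grid.
    """
    x = f.values
    mean_map = anp.mean(x, axis=1, keepdims=True)
    max_map = anp.max(x, axis=1, keepdims=True)
    stacked = anp.concatenate([mean_map, max_map], axis=1)   # N, 2, h, w
    out = conv2d(stacked, params["W"], params["b"], stride=1, pad="same",
                 pad_mode="edge")
    return sigmoid(out[:, 0])                                # N, h, w


def refine(f_fusion: FeatureMap, maps: AttentionMaps) -> FeatureMap:
    """Element-wise modulation ``A_c (x) A_s (x) F_fusion``.

    ``A_c`` broadcasts over space, ``A_s`` over channels.
    """
    x = f_fusion.values
    N, C, h, w = x.shape
    ac, asp = maps.channel_map, maps.spatial_map
    if ac.shape != (N, C):
        raise ShapeError(f"channel map shape {ac.shape} incompatible with {(N, C)}")
    if asp.shape != (N, h, w):
        raise ShapeError(f"spatial map shape {asp.shape} incompatible with {(N, h, w)}")
    out = ac[:, :, None, None] * asp[:, None, :, :] * x
    return FeatureMap(values=out, stream_origin="refined")


def sarm_apply(f_fusion: FeatureMap, params) -> tuple[FeatureMap, AttentionMaps]:
    """Compute both attention maps and return the refined map."""
    maps = AttentionMaps(
        channel_map=channel_attention(f_fusion, params["ch"]),
        spatial_map=spatial_attention(f_fusion, params["sp"]),
    )
    return refine(f_fusion, maps), maps
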