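"""The two parallel feature streams.

The convolutional stream captures fine local texture (a stack of stride-s
conv + ReLU stages); the vision-transformer stream captures global layout
(patch embedding with a learned positional table, then pre-norm transformer
blocks).  Both end up as feature maps on a common ``C x h x w`` grid via
:func:`align_vit_to_map`, which is where fusion picks them up.

All forwards are pure functions of ``(params, input, config)`` and are
deterministic; parameters live in plain nested dicts so that autograd can
differentiate end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import autograd.numpy as anp
import numpy as np

from .config import StreamConfig
from .ops import (
    ShapeError,
    as_array,
    bilinear_resize,
    conv2d,
    he_init,
    layer_norm,
    linear,
    relu,
    softmax,
    xavier_init,
)


@dataclass
class FeatureMap:
    """A ``(N, C, h, w)`` activation grid tagged with its origin."""

    values: anp.ndarray
    stream_origin: str  # {"cnn", "vit", "fused", "refined"}


@dataclass
class TokenSequence:
    """``(N, n_patches, embed_dim)`` patch tokens plus their spatial grid."""

    tokens: anp.ndarray
    grid_shape: Tuple[int, int]


# ---------------------------------------------------------------------------
# parameter construction


def init_cnn_params(cfg: StreamConfig, rng: np.random.Generator, in_channels: int = 1):
    params = []
    cin = in_channels
    k = cfg.kernel_size
    for cout, _stride in cfg.cnn_blocks:
        params.append(
            {
                "W": he_init(rng, (cout, cin, k, k), fan_in=cin * k * k),
                "b": np.zeros(cout),
            }
        )
        cin = cout
    return params


def init_vit_params(cfg: StreamConfig, image_size: int, rng: np.random.Generator,
                    in_channels: int = 1):
    if image_size % cfg.patch_size != 0:
        raise ShapeError(
            f"image_size {image_size} is not divisible by patch_size {cfg.patch_size}"
        )
    g = image_size // cfg.patch_size
    D = cfg.embed_dim
    pdim = cfg.patch_size * cfg.patch_size * in_channels
    mlp = int(round(D * cfg.mlp_ratio))
    blocks = []
    for _ in range(cfg.n_layers):
        blocks.append(
            {
                "ln1_g": np.ones(D), "ln1_b": np.zeros(D),
                "Wq": xavier_init(rng, (D, D), D, D), "bq": np.zeros(D),
                "Wk": xavier_init(rng, (D, D), D, D), "bk": np.zeros(D),
                "Wv": xavier_init(rng, (D, D), D, D), "bv": np.zeros(D),
                "Wo": xavier_init(rng, (D, D), D, D), "bo": np.zeros(D),
                "ln2_g": np.ones(D), "ln2_b": np.zeros(D),
                "W1": he_init(rng, (D, mlp), D), "b1": np.zeros(mlp),
                "W2": xavier_init(rng, (mlp, D), mlp, D), "b2": np.zeros(D),
            }
        )
    return {
        "patch_W": xavier_init(rng, (pdim, D), pdim, D),
        "patch_b": np.zeros(D),
        "pos": rng.normal(0.0, 0.02, size=(g * g, D)),
        "blocks": blocks,
    }


def init_align_params(cfg: StreamConfig, rng: np.random.Generator):
    D, C = cfg.embed_dim, cfg.common_channels
    return {"W": xavier_init(rng, (D, C), D, C), "b": np.zeros(C)}


# ---------------------------------------------------------------------------
# CNN stream


def cnn_forward(image_batch, params, cfg: StreamConfig) -> FeatureMap:
    """Run the convolutional stream: stride-s conv + ReLU per block.

    ``image_batch`` is ``(N, H, W)`` or ``(N, C_in, H, W)`` in [0, 1].
    The spatial size shrinks by the product of block strides.  By default
    convolutions use circular padding, so the stream is exactly
    (cyclically) translation-covariant: its pooled features carry local
    texture statistics but no absolute position — position awareness is the
    ViT stream's job, which is what makes the two streams complementary.
    ``StreamConfig.conv_padding`` switches to zero or edge padding.
    """
    x = image_batch if image_batch.ndim == 4 else image_batch[:, None, :, :]
    for i, ((_, stride), p) in enumerate(zip(cfg.cnn_blocks, params)):
        h = x.shape[2]
        if h % stride != 0:
            raise ShapeError(
                f"cnn block {i}: input spatial size {h} not divisible by stride {stride}"
            )
        x = relu(conv2d(x, p["W"], p["b"], stride=stride, pad="same",
                        pad_mode=cfg.conv_padding))
    return FeatureMap(values=x, stream_origin="cnn")


# ---------------------------------------------------------------------------
# ViT stream


def extract_patches(image_batch, patch_size: int):
    """Split ``(N, C, H, W)`` into flattened non-overlapping patches.

    Returns ``(N, n_patches, patch_size**2 * C)`` in row-major grid order,
    each patch flattened channel-first then row-major.
    """
    x = image_batch if image_batch.ndim == 4 else image_batch[:, None, :, :]
    N, C, H, W = x.shape
    p = patch_size
    if H % p != 0 or W % p != 0:
        raise ShapeError(f"image size {H}x{W} not divisible by patch size {p}")
    gh, gw = H // p, W // p
    x = anp.reshape(x, (N, C, gh, p, gw, p))
    x = anp.transpose(x, (0, 2, 4, 1, 3, 5))       # N, gh, gw, C, p, p
    return anp.reshape(x, (N, gh * gw, C * p * p)), (gh, gw)


def patch_embed(image_batch, params, cfg: StreamConfig) -> TokenSequence:
    """Linearly embed non-overlapping patches and add positional encodings."""
    flat, grid = extract_patches(image_batch, cfg.patch_size)
    if flat.shape[2] != params["patch_W"].shape[0]:
        raise ShapeError(
            f"patch dim {flat.shape[2]} does not match embedding "
            f"input dim {params['patch_W'].shape[0]}"
        )
    tokens = linear(flat, params["patch_W"], params["patch_b"]) + params["pos"][None]
    return TokenSequence(tokens=tokens, grid_shape=grid)


def scaled_dot_attention(Q, K, V, d_k: int):
    """softmax(Q K^T / sqrt(d_k)) V on the last two axes.

    Works for single matrices ``(n_q, d)`` or batched stacks
    ``(..., n_q, d)``; each softmax row sums to one.
    """
    Q, K, V = as_array(Q), as_array(K), as_array(V)
    if Q.shape[-1] != K.shape[-1]:
        raise ShapeError(f"Q inner dim {Q.shape[-1]} != K inner dim {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ShapeError(f"K rows {K.shape[-2]} != V rows {V.shape[-2]}")
    logits = anp.matmul(Q, anp.swapaxes(K, -1, -2)) / anp.sqrt(float(d_k))
    return anp.matmul(softmax(logits, axis=-1), V)


def _mhsa(x, p, n_heads: int):
    N, P, D = x.shape
    dh = D // n_heads

    def split(z):
        return anp.transpose(anp.reshape(z, (N, P, n_heads, dh)), (0, 2, 1, 3))

    q = split(linear(x, p["Wq"], p["bq"]))
    k = split(linear(x, p["Wk"], p["bk"]))
    v = split(linear(x, p["Wv"], p["bv"]))
    out = scaled_dot_attention(q, k, v, dh)        # N, heads, P, dh
    out = anp.reshape(anp.transpose(out, (0, 2, 1, 3)), (N, P, D))
    return linear(out, p["Wo"], p["bo"])


def vit_forward(tokens: TokenSequence, params, cfg: StreamConfig) -> TokenSequence:
    """Pre-norm transformer encoder; token count and grid are preserved."""
    x = tokens.tokens
    for p in params["blocks"]:
        x = x + _mhsa(layer_norm(x, p["ln1_g"], p["ln1_b"]), p, cfg.n_heads)
        h = layer_norm(x, p["ln2_g"], p["ln2_b"])
        x = x + linear(relu(linear(h, p["W1"], p["b1"])), p["W2"], p["b2"])
    return TokenSequence(tokens=x, grid_shape=tokens.grid_shape)


def align_vit_to_map(tokens: TokenSequence, params, target_shape: Tuple[int, int],
                     C: int) -> FeatureMap:
    """Project tokens to ``C`` channels and resample onto the CNN grid.

    Reshape (grid order) -> 1x1 linear projection -> bilinear resize.
    """
    if tokens.grid_shape is None:
        raise ShapeError("TokenSequence has no grid_shape; cannot align to a map")
    gh, gw = tokens.grid_shape
    proj = linear(tokens.tokens, params["W"], params["b"])   # N, P, C
    N = proj.shape[0]
    fmap = anp.transpose(anp.reshape(proj, (N, gh, gw, C)), (0, 3, 1, 2))
    fmap = bilinear_resize(fmap, target_shape[0], target_shape[1])
    return FeatureMap(values=fmap, stream_origin="vit")
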