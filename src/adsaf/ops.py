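"""Differentiable array operations used by both feature streams.

The whole network is expressed as pure functions of a nested parameter
pytree (dicts/lists of numpy arrays) and differentiated with ``autograd``'s
reverse mode, so every forward here must stay inside ``autograd.numpy``
primitives.  Convolution is im2col + matmul; bilinear resampling uses the
align-corners convention (output corners sample input corners exactly).
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np


class ShapeError(ValueError):
    """Raised when tensor shapes are incompatible with an operation."""


def as_array(x):
    """Coerce lists/scalars to arrays while leaving autograd boxes untouched."""
    return x if hasattr(x, "ndim") else np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# convolution


def _im2col_indices(H, W, k, stride, pad):
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    if Ho < 1 or Wo < 1:
        raise ShapeError(
            f"conv with kernel {k}, stride {stride} cannot be applied to a "
            f"{H}x{W} input (output would be {Ho}x{Wo})"
        )
    i0 = np.repeat(np.arange(k), k)
    j0 = np.tile(np.arange(k), k)
    i1 = stride * np.repeat(np.arange(Ho), Wo)
    j1 = stride * np.tile(np.arange(Wo), Ho)
    ii = i0[:, None] + i1[None, :]
    jj = j0[:, None] + j1[None, :]
    return ii, jj, Ho, Wo


def conv2d(x, W, b, stride=1, pad="same", pad_mode="constant"):
    """2-D convolution (cross-correlation) of an NCHW batch.

    Parameters
    ----------
    x : (N, C_in, H, W) array
    W : (C_out, C_in, k, k) kernel
    b : (C_out,) bias
    pad : "same" for k//2 zero padding, or an integer
    """
    N, Cin, H, Wd = x.shape
    Cout, CinW, k, k2 = W.shape
    if k != k2:
        raise ShapeError(f"kernel must be square, got {k}x{k2}")
    if CinW != Cin:
        raise ShapeError(
            f"kernel expects {CinW} input channels but input has {Cin}"
        )
    p = k // 2 if pad == "same" else int(pad)
    if p == 0:
        xp = x
    elif pad_mode == "constant":
        xp = anp.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), "constant")
    elif pad_mode == "edge":
        # replicate borders via concatenation (autograd's pad vjp is
        # constant-mode only); preserves spatially constant inputs
        xp = anp.concatenate([x[:, :, :1, :]] * p + [x] + [x[:, :, -1:, :]] * p, axis=2)
        xp = anp.concatenate([xp[:, :, :, :1]] * p + [xp] + [xp[:, :, :, -1:]] * p, axis=3)
    elif pad_mode == "wrap":
        # circular padding: makes convolution exactly (cyclically)
        # translation-covariant, with no border-position leakage
        xp = anp.concatenate([x[:, :, -p:, :], x, x[:, :, :p, :]], axis=2)
        xp = anp.concatenate([xp[:, :, :, -p:], xp, xp[:, :, :, :p]], axis=3)
    else:
        raise ValueError(f"unsupported pad_mode {pad_mode!r}")
    ii, jj, Ho, Wo = _im2col_indices(H, Wd, k, stride, p)
    cols = anp.reshape(xp[:, :, ii, jj], (N, Cin * k * k, Ho * Wo))
    Wm = anp.reshape(W, (Cout, Cin * k * k))
    out = anp.einsum("of,nfp->nop", Wm, cols) + b[None, :, None]
    return anp.reshape(out, (N, Cout, Ho, Wo))


# ---------------------------------------------------------------------------
# basic layers


def linear(x, W, b):
    """Affine map on the last axis: x @ W + b."""
    return anp.matmul(x, W) + b


def relu(x):
    return anp.maximum(x, 0.0)


def sigmoid(x):
    # numerically symmetric formulation
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def softmax(x, axis=-1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    return z - anp.log(anp.sum(anp.exp(z), axis=axis, keepdims=True))


def layer_norm(x, gamma, beta, eps=1e-5):
    """Normalize over the last axis, then scale and shift."""
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return gamma * (x - mu) / anp.sqrt(var + eps) + beta


def global_avg_pool(fmap):
    """(N, C, h, w) -> (N, C) spatial mean."""
    return anp.mean(fmap, axis=(2, 3))


def rms_normalize(fmap, eps=1e-6):
    """Scale each sample's feature map to unit root-mean-square activation.

    Puts both streams on a common amplitude so that fusion weights compare
    feature *content* rather than raw activation scale.
    """
    rms = anp.sqrt(anp.mean(fmap ** 2, axis=(1, 2, 3), keepdims=True) + eps)
    return fmap / rms


# ---------------------------------------------------------------------------
# bilinear resampling (align-corners)


def _resize_axis_weights(n_in: int, n_out: int):
    """Source indices and weights for 1-D align-corners bilinear resampling."""
    if n_in == 1:
        lo = np.zeros(n_out, dtype=int)
        return lo, lo, np.ones(n_out)
    if n_out == 1:
        pos = np.array([(n_in - 1) / 2.0])
    else:
        pos = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.floor(pos).astype(int)
    lo = np.clip(lo, 0, n_in - 2)
    frac = pos - lo
    return lo, lo + 1, frac


def bilinear_resize(fmap, out_h: int, out_w: int):
    """Resize (N, C, h, w) to (N, C, out_h, out_w); differentiable.

    Uses the align-corners convention: output corner pixels equal input
    corner pixels, interior values are separable linear interpolations.
    """
    N, C, h, w = fmap.shape
    if (h, w) == (out_h, out_w):
        return fmap
    ylo, yhi, wy = _resize_axis_weights(h, out_h)
    xlo, xhi, wx = _resize_axis_weights(w, out_w)
    wy = wy[:, None]
    wx = wx[None, :]
    tl = fmap[:, :, ylo][:, :, :, xlo]
    tr = fmap[:, :, ylo][:, :, :, xhi]
    bl = fmap[:, :, yhi][:, :, :, xlo]
    br = fmap[:, :, yhi][:, :, :, xhi]
    top = tl * (1 - wx) + tr * wx
    bot = bl * (1 - wx) + br * wx
    return top * (1 - wy) + bot * wy


# ---------------------------------------------------------------------------
# parameter initialization

def he_init(rng: np.random.Generator, shape, fan_in: int):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def xavier_init(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)
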