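"""Entropy-regularized adaptive fusion of the CNN and ViT streams.

A two-layer gate maps the pooled, concatenated stream features to a single
per-image weight ``alpha = sigmoid(W2 relu(W1 [f_cnn ++ f_vit] + b1) + b2)``
in [0, 1]; the fused map is the convex combination
``alpha * F_cnn + (1 - alpha) * F_vit``.  The batch-mean binary entropy of
alpha is the fusion regularizer: minimizing it pushes the gate toward a
confident choice of stream, so each image ends up dominated by whichever
representation (local texture vs global layout) actually carries its class
signal.  Because alpha is computed from the pooled features of both
streams, the entropy term back-propagates into both extractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .ops import (
    ShapeError,
    as_array,
    global_avg_pool,
    he_init,
    linear,
    relu,
    sigmoid,
    xavier_init,
)
from .streams import FeatureMap

#: clamp for alpha inside the entropy, so endpoint gates contribute ~0 loss
ENTROPY_EPS = 1e-7


@dataclass
class FusionGateOutput:
    """Per-sample gate weights plus their batch entropy (nats)."""

    alpha: anp.ndarray       # (N,)
    batch_entropy: float


def init_gate_params(C: int, hidden: int, rng: np.random.Generator):
    """Gate parameters with a zero-initialized output layer.

    With W2 = b2 = 0 the gate opens at exactly alpha = 0.5, where the
    binary-entropy gradient vanishes: the classification loss must move
    alpha off the fence first, and only then does entropy pressure amplify
    the direction it chose.  This prevents premature convergence to a
    trivial dominance before either stream has learned anything.
    """
    return {
        "W1": he_init(rng, (2 * C, hidden), fan_in=2 * C),
        "b1": np.zeros(hidden),
        "W2": np.zeros((hidden, 1)),
        "b2": np.zeros(1),
    }


def compute_gate(f_cnn: FeatureMap, f_vit: FeatureMap, gate_params) -> FusionGateOutput:
    """Image-specific fusion weight from the pooled, concatenated streams."""
    a, b = f_cnn.values, f_vit.values
    if a.shape != b.shape:
        raise ShapeError(
            f"gate inputs must share shape; got cnn {a.shape} vs vit {b.shape}"
        )
    pooled = anp.concatenate([global_avg_pool(a), global_avg_pool(b)], axis=1)  # N, 2C
    h = relu(linear(pooled, gate_params["W1"], gate_params["b1"]))
    alpha = sigmoid(linear(h, gate_params["W2"], gate_params["b2"]))[:, 0]
    return FusionGateOutput(alpha=alpha, batch_entropy=fusion_entropy(alpha))


def fuse(f_cnn: FeatureMap, f_vit: FeatureMap, alpha) -> FeatureMap:
    """Convex combination ``alpha * F_cnn + (1 - alpha) * F_vit``."""
    a, b = f_cnn.values, f_vit.values
    if a.shape != b.shape:
        raise ShapeError(f"cannot fuse maps of shapes {a.shape} and {b.shape}")
    alpha = as_array(alpha)
    av = np.asarray(getattr(alpha, "_value", alpha), dtype=float)
    if np.any(av < -1e-12) or np.any(av > 1 + 1e-12):
        raise ValueError(f"alpha must lie in [0, 1], got range [{av.min()}, {av.max()}]")
    w = anp.reshape(alpha, (-1, 1, 1, 1)) if alpha.ndim == 1 else alpha
    return FeatureMap(values=w * a + (1.0 - w) * b, stream_origin="fused")


def fusion_entropy(alphas):
    """Batch-mean binary entropy of the gate weights, in nats.

    ``-mean[a ln a + (1-a) ln(1-a)]`` with ``a`` clamped away from the
    endpoints by ``ENTROPY_EPS``; lies in [0, ln 2], with endpoint gates
    contributing ~0 and an undecided gate (a = 0.5) contributing ln 2.

    Each weight is first folded onto the upper half via
    ``0.5 + |a - 0.5|``, so the symmetry H(a) = H(1-a) is bit-exact
    whenever ``a`` and ``1-a`` are exact floating-point complements (e.g.
    any dyadic a); for general floats the asymmetry is bounded by the
    rounding of ``1-a`` itself, about one ulp.
    """
    alphas = as_array(alphas)
    if alphas.size == 0:
        raise ValueError("fusion_entropy of an empty batch is undefined")
    c = anp.clip(0.5 + anp.abs(alphas - 0.5), 0.5, 1.0 - ENTROPY_EPS)
    return -anp.mean(c * anp.log(c) + (1.0 - c) * anp.log(1.0 - c))
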