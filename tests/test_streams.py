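"""Stream forwards against brute-force oracles and structural invariants."""

import autograd.numpy as anp
import numpy as np
import pytest

from adsaf.config import StreamConfig
from adsaf.ops import ShapeError, bilinear_resize, conv2d
from adsaf.streams import (
    TokenSequence,
    align_vit_to_map,
    cnn_forward,
    extract_patches,
    init_align_params,
    init_cnn_params,
    init_vit_params,
    patch_embed,
    scaled_dot_attention,
    vit_forward,
)


def brute_force_conv(img, kernel, stride=1, pad=1, pad_mode="constant"):
    """Direct sliding-window cross-correlation on a single-channel image."""
    k = kernel.shape[0]
    if pad_mode == "wrap":
        img = np.pad(img, pad, mode="wrap")
    else:
        img = np.pad(img, pad)
    H, W = img.shape
    out = []
    for y in range(0, H - k + 1, stride):
        row = []
        for x in range(0, W - k + 1, stride):
            row.append(np.sum(img[y:y + k, x:x + k] * kernel))
        out.append(row)
    return np.asarray(out)


class TestConv:
    def test_matches_sliding_window_oracle_on_printed_patch(self):
        img = np.array([[1., 2., 0., 1., 3.],
                        [0., 1., 2., 2., 1.],
                        [3., 0., 1., 0., 0.],
                        [1., 1., 0., 2., 1.],
                        [2., 0., 3., 1., 0.]])
        kernel = np.array([[1., 0., -1.],
                           [2., 0., -2.],
                           [1., 0., -1.]])
        got = conv2d(img[None, None], kernel[None, None], np.zeros(1), stride=1)
        want = brute_force_conv(img, kernel)
        assert np.allclose(got[0, 0], want)

    def test_strided_conv_matches_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((8, 8))
        kernel = rng.standard_normal((3, 3))
        got = conv2d(img[None, None], kernel[None, None], np.zeros(1), stride=2)
        want = brute_force_conv(img, kernel, stride=2)
        assert np.allclose(got[0, 0], want)

    def test_wrap_padding_matches_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((6, 6))
        kernel = rng.standard_normal((3, 3))
        got = conv2d(img[None, None], kernel[None, None], np.zeros(1),
                     stride=1, pad_mode="wrap")
        want = brute_force_conv(img, kernel, pad_mode="wrap")
        assert np.allclose(got[0, 0], want)

    def test_channel_mismatch_raises(self):
        with pytest.raises(ShapeError, match="channels"):
            conv2d(np.zeros((1, 2, 4, 4)), np.zeros((1, 3, 3, 3)), np.zeros(1))


class TestCnnForward:
    def test_zero_input_zero_kernel_gives_zero_map(self, small_stream):
        params = init_cnn_params(small_stream, np.random.default_rng(0))
        for p in params:
            p["W"][:] = 0.0
        out = cnn_forward(np.zeros((2, 32, 32)), params, small_stream)
        assert np.allclose(out.values, 0.0)
        assert out.stream_origin == "cnn"

    def test_stride_stack_arithmetic(self):
        cfg = StreamConfig(common_channels=8,
                           cnn_blocks=((4, 2), (8, 2), (8, 2), (8, 2)),
                           embed_dim=8, n_heads=2)
        params = init_cnn_params(cfg, np.random.default_rng(0))
        out = cnn_forward(np.zeros((1, 64, 64)), params, cfg)
        assert out.values.shape == (1, 8, 4, 4)

    def test_incompatible_size_names_offending_stage(self, small_stream):
        params = init_cnn_params(small_stream, np.random.default_rng(0))
        with pytest.raises(ShapeError, match="block 1"):
            # 10 -> block0 stride 2 -> 5, block1 stride 2 fails
            cnn_forward(np.zeros((1, 10, 10)), params, small_stream)

    def test_translation_covariance_is_exact_under_cyclic_shift(self):
        cfg = StreamConfig(common_channels=6, cnn_blocks=((6, 1),),
                           embed_dim=8, n_heads=2)
        params = init_cnn_params(cfg, np.random.default_rng(3))
        img = np.random.default_rng(4).random((1, 12, 12))
        base = cnn_forward(img, params, cfg).values
        rolled = cnn_forward(np.roll(img, 3, axis=1), params, cfg).values
        assert np.allclose(np.roll(base, 3, axis=2), rolled)


class TestPatchEmbed:
    def test_token_count_and_grid_forced_by_arithmetic(self):
        cfg = StreamConfig(common_channels=8, cnn_blocks=((8, 2),),
                           patch_size=16, embed_dim=8, n_heads=2)
        params = init_vit_params(cfg, 64, np.random.default_rng(0))
        seq = patch_embed(np.zeros((1, 64, 64)), params, cfg)
        assert seq.tokens.shape == (1, 16, 8)
        assert seq.grid_shape == (4, 4)

    def test_zero_image_zero_pos_zero_bias_gives_zero_tokens(self, small_stream):
        params = init_vit_params(small_stream, 32, np.random.default_rng(0))
        params["pos"][:] = 0.0
        seq = patch_embed(np.zeros((1, 32, 32)), params, small_stream)
        assert np.allclose(seq.tokens, 0.0)

    def test_identity_embedding_reproduces_manual_flattening(self):
        cfg = StreamConfig(common_channels=4, cnn_blocks=((4, 2),),
                           patch_size=2, embed_dim=4, n_heads=2)
        params = init_vit_params(cfg, 4, np.random.default_rng(0))
        params["patch_W"] = np.eye(4)
        params["patch_b"][:] = 0.0
        params["pos"][:] = 0.0
        img = np.arange(16, dtype=float).reshape(1, 4, 4)
        seq = patch_embed(img, params, cfg)
        # manual flattening of the four 2x2 patches, row-major
        want = np.array([[0, 1, 4, 5], [2, 3, 6, 7],
                         [8, 9, 12, 13], [10, 11, 14, 15]], dtype=float)
        assert np.allclose(seq.tokens[0], want)

    def test_indivisible_size_rejected(self, small_stream):
        with pytest.raises(ShapeError, match="divisible"):
            extract_patches(np.zeros((1, 30, 30)), small_stream.patch_size)


class TestScaledDotAttention:
    def test_single_key_returns_that_value_row(self):
        Q = np.array([[5.0, -3.0]])
        K = np.array([[0.1, 0.2]])
        V = np.array([[7.0, 8.0, 9.0]])
        out = scaled_dot_attention(Q, K, V, 2)
        assert np.allclose(out, V)

    def test_equal_logits_give_unweighted_mean(self):
        Q = np.zeros((2, 3))
        K = np.random.default_rng(0).random((4, 3))
        V = np.random.default_rng(1).random((4, 5))
        out = scaled_dot_attention(Q, K, V, 3)
        assert np.allclose(out, np.tile(V.mean(axis=0), (2, 1)))

    def test_two_token_hand_example_matches_brute_force(self):
        # hand-set example, d_k = 2
        Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        K = np.array([[1.0, 1.0], [0.0, 2.0]])
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        got = scaled_dot_attention(Q, K, V, 2)
        # brute force with explicit scalar arithmetic
        import math
        s = math.sqrt(2.0)
        want = np.empty((2, 2))
        for i in range(2):
            l0 = (Q[i, 0] * K[0, 0] + Q[i, 1] * K[0, 1]) / s
            l1 = (Q[i, 0] * K[1, 0] + Q[i, 1] * K[1, 1]) / s
            m = max(l0, l1)
            w0, w1 = math.exp(l0 - m), math.exp(l1 - m)
            z = w0 + w1
            want[i] = [(w0 * V[0, 0] + w1 * V[1, 0]) / z,
                       (w0 * V[0, 1] + w1 * V[1, 1]) / z]
        assert np.allclose(got, want)

    def test_softmax_rows_sum_to_one_implicitly(self):
        # output of attention over constant V equals that constant
        V = np.full((3, 4), 2.5)
        out = scaled_dot_attention(np.random.default_rng(0).random((5, 2)),
                                   np.random.default_rng(1).random((3, 2)), V, 2)
        assert np.allclose(out, 2.5)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ShapeError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 4)),
                                 np.zeros((2, 4)), 3)


class TestVitForward:
    def test_zero_layers_is_identity(self):
        cfg = StreamConfig(common_channels=8, cnn_blocks=((8, 2),),
                           embed_dim=8, n_heads=2, n_layers=0)
        params = init_vit_params(cfg, 32, np.random.default_rng(0))
        tokens = TokenSequence(np.random.default_rng(2).random((1, 16, 8)), (4, 4))
        out = vit_forward(tokens, params, cfg)
        assert np.array_equal(out.tokens, tokens.tokens)
        assert out.grid_shape == (4, 4)

    def test_permutation_equivariance_of_encoder(self, small_stream):
        params = init_vit_params(small_stream, 32, np.random.default_rng(0))
        tokens = np.random.default_rng(5).random((1, 16, small_stream.embed_dim))
        perm = np.random.default_rng(6).permutation(16)
        base = vit_forward(TokenSequence(tokens, (4, 4)), params, small_stream)
        permed = vit_forward(TokenSequence(tokens[:, perm], (4, 4)),
                             params, small_stream)
        assert np.allclose(base.tokens[:, perm], permed.tokens)

    def test_single_layer_matches_composed_oracles(self):
        from adsaf.ops import layer_norm, linear, relu
        cfg = StreamConfig(common_channels=4, cnn_blocks=((4, 2),),
                           embed_dim=4, n_heads=1, n_layers=1, mlp_ratio=2.0)
        params = init_vit_params(cfg, 8, np.random.default_rng(0))
        x = np.random.default_rng(7).random((1, 4, 4))
        got = vit_forward(TokenSequence(x, (2, 2)), params, cfg).tokens
        # oracle: explicit pre-norm block composition
        b = params["blocks"][0]
        h = layer_norm(x, b["ln1_g"], b["ln1_b"])
        q = linear(h, b["Wq"], b["bq"])
        k = linear(h, b["Wk"], b["bk"])
        v = linear(h, b["Wv"], b["bv"])
        att = scaled_dot_attention(q[0], k[0], v[0], 4)[None]
        x1 = x + linear(att, b["Wo"], b["bo"])
        h2 = layer_norm(x1, b["ln2_g"], b["ln2_b"])
        want = x1 + linear(relu(linear(h2, b["W1"], b["b1"])), b["W2"], b["b2"])
        assert np.allclose(got, want)


class TestAlign:
    def test_identity_projection_same_grid_is_pure_reshape(self):
        cfg = StreamConfig(common_channels=4, cnn_blocks=((4, 2),),
                           embed_dim=4, n_heads=2)
        params = {"W": np.eye(4), "b": np.zeros(4)}
        tokens = np.random.default_rng(0).random((1, 16, 4))
        out = align_vit_to_map(TokenSequence(tokens, (4, 4)), params, (4, 4), 4)
        want = tokens.reshape(1, 4, 4, 4).transpose(0, 3, 1, 2)
        assert np.allclose(out.values, want)
        assert out.stream_origin == "vit"

    def test_constant_tokens_give_constant_map(self, small_stream):
        params = init_align_params(small_stream, np.random.default_rng(0))
        tokens = np.full((1, 16, small_stream.embed_dim), 0.7)
        out = align_vit_to_map(TokenSequence(tokens, (4, 4)), params, (8, 8),
                               small_stream.common_channels)
        per_channel = out.values[0].reshape(small_stream.common_channels, -1)
        assert np.allclose(per_channel, per_channel[:, :1])

    def test_bilinear_upsampling_matches_hand_table(self):
        # corners 0, 3, 6, 9: align-corners interpolation gives 3*wx + 6*wy
        fmap = np.array([[[[0.0, 3.0], [6.0, 9.0]]]])
        got = bilinear_resize(fmap, 4, 4)[0, 0]
        w = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        want = 3.0 * w[None, :] + 6.0 * w[:, None]
        assert np.allclose(got, want)

    def test_missing_grid_shape_rejected(self):
        with pytest.raises(ShapeError, match="grid_shape"):
            align_vit_to_map(TokenSequence(np.zeros((1, 4, 4)), None),
                             {"W": np.eye(4), "b": np.zeros(4)}, (2, 2), 4)
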