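"""Forward-pass contracts of the channel-attention BiLSTM."""

import numpy as np
import pytest

from eegpf._autodiff import Tensor
from eegpf.network import (ModelConfig, ModelParams, channel_attention,
                           channel_embed, forward_batch, init_params,
                           load_checkpoint, parameter_count, predict_proba,
                           save_checkpoint, spatial_encode, temporal_encode)


@pytest.fixture
def cfg():
    return ModelConfig(n_bands=3, n_channels=4, n_segments=3, d_embed=5,
                       d_attn=4, u_spatial=4, k_compress=3, v_temporal=5, seed=0)


@pytest.fixture
def params(cfg):
    return init_params(cfg)


class TestChannelEmbed:
    def test_identity_map(self, rng):
        cfg = ModelConfig(n_bands=3, n_channels=4, n_segments=2, d_embed=3,
                          d_attn=2, u_spatial=2, k_compress=2, v_temporal=2)
        p = init_params(cfg)
        p["embed_M"].data[:] = np.eye(3)[None]
        p["embed_b"].data[:] = 0.0
        x = Tensor(rng.standard_normal((4, 3)))  # (M, F)
        A = channel_embed(x, p)
        np.testing.assert_allclose(A.data, x.data, atol=1e-12)

    def test_zero_input_gives_bias(self, params, cfg, rng):
        params["embed_b"].data[:] = rng.standard_normal(params["embed_b"].shape)
        A = channel_embed(Tensor(np.zeros((4, 3))), params)
        np.testing.assert_allclose(A.data, params["embed_b"].data, atol=1e-12)

    def test_per_channel_locality(self, params, rng):
        x = rng.standard_normal((4, 3))
        x2 = x.copy()
        x2[3] += 1.0
        A1 = channel_embed(Tensor(x), params).data
        A2 = channel_embed(Tensor(x2), params).data
        np.testing.assert_array_equal(A1[:3], A2[:3])
        assert np.abs(A1[3] - A2[3]).max() > 0

    def test_shape_mismatch_names_dimension(self, params):
        with pytest.raises(ValueError, match="channels"):
            channel_embed(Tensor(np.zeros((5, 3))), params)
        with pytest.raises(ValueError, match="band"):
            channel_embed(Tensor(np.zeros((4, 7))), params)


class TestChannelAttention:
    def test_single_channel_weight_is_one(self, rng):
        cfg = ModelConfig(n_bands=2, n_channels=1, n_segments=2, d_embed=3,
                          d_attn=2, u_spatial=2, k_compress=1, v_temporal=2)
        p = init_params(cfg)
        A = Tensor(rng.standard_normal((1, 3)))
        A_hat, W = channel_attention(A, p)
        np.testing.assert_allclose(W.data, [[1.0]], atol=1e-12)
        np.testing.assert_allclose(A_hat.data, A.data, atol=1e-12)

    def test_uniform_scores_mix_equally(self, params, rng):
        params["attn_Q"].data[:] = 0.0  # raw scores all zero -> uniform columns
        A = Tensor(rng.standard_normal((4, 5)))
        A_hat, W = channel_attention(A, params)
        np.testing.assert_allclose(W.data, 0.25, atol=1e-12)
        np.testing.assert_allclose(A_hat.data,
                                   np.tile(A.data.mean(axis=0), (4, 1)), atol=1e-12)

    def test_column_stochastic_random_inputs(self, params, rng):
        A = Tensor(rng.standard_normal((7, 4, 5)))
        _, W = channel_attention(A, params)
        np.testing.assert_allclose(W.data.sum(axis=-2), 1.0, atol=1e-6)
        assert (W.data > 0).all() and (W.data < 1).all()

    def test_ablation_skips(self, params, rng):
        A = Tensor(rng.standard_normal((4, 5)))
        A_hat, W = channel_attention(A, params, use_channel_attention=False)
        assert W is None
        assert A_hat is A

    def test_nonfinite_scores_error(self, params):
        A = Tensor(np.full((4, 5), np.nan))
        with pytest.raises(FloatingPointError):
            channel_attention(A, params)


class TestSpatialEncode:
    def test_output_shape(self, params, cfg, rng):
        A = Tensor(rng.standard_normal((6, 4, 5)))
        out = spatial_encode(A, params, cfg)
        assert out.shape == (6, 2 * cfg.u_spatial, cfg.k_compress)

    def test_relu_clamps_negative_preactivation(self, params, cfg, rng):
        params["comp_G"].data[:] = 0.0
        params["comp_b"].data[:] = -5.0
        A = Tensor(rng.standard_normal((2, 4, 5)))
        out = spatial_encode(A, params, cfg)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_not_invariant_to_channel_order(self, params, cfg, rng):
        A = rng.standard_normal((1, 4, 5))
        out1 = spatial_encode(Tensor(A), params, cfg).data
        out2 = spatial_encode(Tensor(A[:, ::-1].copy()), params, cfg).data
        assert np.abs(out1 - out2).max() > 1e-8

    def test_wrong_channel_count_rejected(self, params, cfg, rng):
        with pytest.raises(ValueError):
            spatial_encode(Tensor(rng.standard_normal((1, 5, 5))), params, cfg)


class TestTemporalEncode:
    def test_flatten_length_and_output(self, params, cfg, rng):
        segs = [Tensor(rng.standard_normal((2, 2 * cfg.u_spatial, cfg.k_compress)))
                for _ in range(cfg.n_segments)]
        out = temporal_encode(segs, params, cfg)
        assert out.shape == (2, 2 * cfg.v_temporal)
        assert np.all(np.isfinite(out.data))

    def test_single_segment_degenerate(self, rng):
        cfg1 = ModelConfig(n_bands=2, n_channels=3, n_segments=1, d_embed=3,
                           d_attn=2, u_spatial=2, k_compress=2, v_temporal=3)
        p1 = init_params(cfg1)
        segs = [Tensor(rng.standard_normal((1, 4, 2)))]
        out = temporal_encode(segs, p1, cfg1)
        assert np.all(np.isfinite(out.data))

    def test_sensitive_to_first_segment(self, params, cfg, rng):
        segs = [rng.standard_normal((1, 2 * cfg.u_spatial, cfg.k_compress))
                for _ in range(cfg.n_segments)]
        out1 = temporal_encode([Tensor(s) for s in segs], params, cfg).data
        segs[0] = segs[0] + 1.0
        out2 = temporal_encode([Tensor(s) for s in segs], params, cfg).data
        assert np.abs(out1 - out2).max() > 1e-8

    def test_wrong_segment_count_rejected(self, params, cfg, rng):
        with pytest.raises(ValueError):
            temporal_encode([Tensor(rng.standard_normal((1, 8, 3)))] * 2, params, cfg)


class TestPredictProba:
    def test_probabilities_normalized(self, params, cfg, rng):
        X = rng.standard_normal((3, 4, 3))
        probs = predict_proba(X, params, cfg)
        assert probs.shape == (2,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert ((probs > 0) & (probs < 1)).all()

    def test_zero_classifier_gives_uniform(self, params, cfg, rng):
        params["cls_G"].data[:] = 0.0
        params["cls_b"].data[:] = 0.0
        probs = predict_proba(rng.standard_normal((3, 4, 3)), params, cfg)
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_deterministic_forward(self, cfg, rng):
        X = rng.standard_normal((3, 4, 3))
        p1, p2 = init_params(cfg), init_params(cfg)
        out1 = predict_proba(X, p1, cfg)
        out2 = predict_proba(X, p2, cfg)
        np.testing.assert_array_equal(out1, out2)

    def test_attention_matrices_returned_per_segment(self, params, cfg, rng):
        X = rng.standard_normal((3, 4, 3))
        probs, W = predict_proba(X, params, cfg, return_attention=True)
        assert W.shape == (cfg.n_segments, 4, 4)
        np.testing.assert_allclose(W.sum(axis=-2), 1.0, atol=1e-6)

    def test_ablation_is_skip_not_identity(self, cfg, rng):
        # the no-attention variant equals the attention variant only if the
        # latter is forced to W = I; generic weights differ
        from dataclasses import replace
        X = rng.standard_normal((3, 4, 3))
        cfg_off = replace(cfg, use_channel_attention=False)
        p_on = init_params(cfg)
        p_off = init_params(cfg_off)
        # share every non-attention parameter
        for k in p_off:
            p_off[k].data[:] = p_on[k].data
        probs_on = predict_proba(X, p_on, cfg)
        probs_off = predict_proba(X, p_off, cfg_off)
        assert np.abs(probs_on - probs_off).max() > 1e-9

    def test_shape_mismatch_rejected(self, params, cfg):
        with pytest.raises(ValueError, match="shape"):
            predict_proba(np.zeros((3, 4, 4)), params, cfg)


class TestParameterCount:
    @pytest.mark.parametrize("use_attn", [True, False])
    def test_closed_form_matches_actual(self, use_attn):
        cfg = ModelConfig(n_bands=5, n_channels=8, n_segments=9, d_embed=6,
                          d_attn=7, u_spatial=5, k_compress=4, v_temporal=6,
                          use_channel_attention=use_attn)
        params = init_params(cfg)
        assert parameter_count(cfg) == sum(t.data.size for t in params.values())


class TestCheckpoint:
    def test_round_trip(self, tmp_path, cfg, params, rng):
        X = rng.standard_normal((3, 4, 3))
        before = predict_proba(X, params, cfg)
        path = tmp_path / "model.json"
        save_checkpoint(path, cfg, params)
        cfg2, params2 = load_checkpoint(path)
        assert cfg2 == cfg
        np.testing.assert_array_equal(predict_proba(X, params2, cfg2), before)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(n_bands=0)
    with pytest.raises(ValueError):
        ModelConfig(n_classes=1)
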