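"""Transformer architecture: attention math, factorized blocks, invariants."""

import numpy as np
import pytest

from hsipath.model import (
    ModelConfig,
    SpectralSpatialTransformer,
    embed_patches,
    extract_patches,
    forward_classify,
    parameter_count,
    scaled_attention,
    tiny_config,
)


def brute_force_attention(Q, K, V, d):
    """Per-token-pair loop oracle for one (seq, dim) instance."""
    n = Q.shape[0]
    att = np.zeros((n, n))
    for i in range(n):
        scores = np.array([Q[i] @ K[j] / np.sqrt(d) for j in range(n)])
        e = np.exp(scores - scores.max())
        att[i] = e / e.sum()
    out = np.zeros_like(V)
    for i in range(n):
        for j in range(n):
            out[i] += att[i, j] * V[j]
    return out, att


class TestScaledAttention:
    def test_single_token(self):
        out, att = scaled_attention(np.ones((1, 4)), np.ones((1, 4)), np.full((1, 4), 2.0))
        np.testing.assert_allclose(att, [[1.0]])
        np.testing.assert_allclose(out, [[2.0] * 4])

    def test_equal_scores_average_values(self):
        Q = np.zeros((2, 4))
        K = np.random.default_rng(0).normal(size=(2, 4))
        V = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        out, att = scaled_attention(Q, K, V)
        np.testing.assert_allclose(att, 0.5)  # uniform over the two tokens
        np.testing.assert_allclose(out, np.tile((V[0] + V[1]) / 2.0, (2, 1)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, d = rng.integers(2, 9), 4
        Q, K, V = rng.normal(size=(3, n, d))
        out, att = scaled_attention(Q, K, V, d)
        out_o, att_o = brute_force_attention(Q, K, V, d)
        np.testing.assert_allclose(att, att_o, atol=1e-5)
        np.testing.assert_allclose(out, out_o, atol=1e-5)
        np.testing.assert_allclose(att.sum(axis=1), 1.0, atol=1e-6)
        assert (att >= 0).all()


class TestEmbedding:
    def test_token_counts(self):
        cfg = ModelConfig(image_px=224, patch_px=16, n_bands=2, embed_dim=16, n_heads=2, depth=1)
        assert cfg.n_tokens == 196
        assert tiny_config(image_px=56, patch_px=8).n_tokens == 49

    def test_zero_cube_tokens_are_bias_plus_positions(self):
        cfg = tiny_config(image_px=16, patch_px=8, n_bands=2, embed_dim=8, n_heads=2, depth=1)
        m = SpectralSpatialTransformer(cfg)
        x, cls = embed_patches(np.zeros((1, 16, 16, 2)), m)
        expect = (
            m.params["patch_embed/b"][None, None, None, :]
            + m.params["pos_embed"][None, None, :, :]
            + m.params["band_embed"][None, :, None, :]
        )
        np.testing.assert_allclose(x, np.broadcast_to(expect, x.shape), atol=1e-12)
        np.testing.assert_allclose(cls[0], m.params["cls_token"])

    def test_patch_order_row_major(self):
        cfg = tiny_config(image_px=4, patch_px=2, n_bands=1, embed_dim=4, n_heads=2, depth=1)
        img = np.arange(16, dtype=float).reshape(1, 4, 4, 1)
        p = extract_patches(img, cfg)
        np.testing.assert_array_equal(p[0, 0, 0], [0, 1, 4, 5])
        np.testing.assert_array_equal(p[0, 0, 1], [2, 3, 6, 7])
        np.testing.assert_array_equal(p[0, 0, 2], [8, 9, 12, 13])

    def test_shape_mismatch_rejected(self):
        cfg = tiny_config()
        m = SpectralSpatialTransformer(cfg)
        with pytest.raises(ValueError, match="does not match"):
            m.forward(np.zeros((1, 32, 32, 8)))


@pytest.fixture(scope="module")
def tiny_model():
    return SpectralSpatialTransformer(
        tiny_config(image_px=24, patch_px=8, n_bands=3, embed_dim=16, n_heads=2, depth=2)
    )


class TestForward:
    def test_probabilities_sum_to_one(self, tiny_model):
        x = np.random.default_rng(0).random((3, 24, 24, 3))
        p = tiny_model.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_eval_determinism(self, tiny_model):
        x = np.random.default_rng(1).random((2, 24, 24, 3))
        np.testing.assert_array_equal(
            tiny_model.predict_proba(x), tiny_model.predict_proba(x)
        )

    def test_forward_classify_single_cube(self, tiny_model):
        cube = np.random.default_rng(2).random((24, 24, 3))
        p = forward_classify(cube, tiny_model)
        assert p.shape == (2,)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_across_bands_gives_uniform_spectral_attention(self):
        cfg = tiny_config(
            image_px=24, patch_px=8, n_bands=4, embed_dim=16, n_heads=2, depth=1,
            band_pos_embed=False,
        )
        m = SpectralSpatialTransformer(cfg)
        band_img = np.random.default_rng(3).random((24, 24, 1))
        x = np.repeat(band_img, 4, axis=2)[None]
        cap = {}
        m.forward(x, capture=cap)
        spec = cap["spectral"][0]  # (N, heads, B, B)
        np.testing.assert_allclose(spec, 1.0 / 4.0, atol=1e-10)

    def test_band_permutation_equivariance_without_band_encoding(self):
        cfg = tiny_config(
            image_px=24, patch_px=8, n_bands=4, embed_dim=16, n_heads=2, depth=2,
            band_pos_embed=False,
        )
        m = SpectralSpatialTransformer(cfg)
        x = np.random.default_rng(4).random((2, 24, 24, 4))
        perm = np.array([2, 0, 3, 1])
        p1 = m.predict_proba(x)
        p2 = m.predict_proba(x[:, :, :, perm])
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_captured_attention_rows_stochastic(self, tiny_model):
        x = np.random.default_rng(5).random((1, 24, 24, 3))
        cap = {}
        tiny_model.forward(x, capture=cap)
        for group in ("spectral", "spatial"):
            for layer in cap[group]:
                assert (layer >= 0).all()
                np.testing.assert_allclose(layer.sum(axis=-1), 1.0, atol=1e-6)

    def test_nan_activation_reported(self, tiny_model):
        broken = SpectralSpatialTransformer(tiny_model.cfg, {
            k: v.copy() for k, v in tiny_model.params.items()
        })
        broken.params["head/W"][0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="head"):
            broken.forward(np.zeros((1, 24, 24, 3)))


class TestParameters:
    @pytest.mark.parametrize(
        "cfg",
        [
            tiny_config(),
            tiny_config(image_px=24, patch_px=8, n_bands=3, embed_dim=16, n_heads=2,
                        depth=2, band_pos_embed=False),
        ],
    )
    def test_closed_form_parameter_count(self, cfg):
        m = SpectralSpatialTransformer(cfg)
        actual = sum(v.size for v in m.params.values())
        assert actual == parameter_count(cfg)

    def test_init_seeded(self):
        a = SpectralSpatialTransformer(tiny_config(init_seed=5)).params
        b = SpectralSpatialTransformer(tiny_config(init_seed=5)).params
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_invalid_configs(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(image_px=224, patch_px=15)
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(embed_dim=65, n_heads=8)


class TestCheckpointing:
    def test_save_load_round_trip(self, tmp_path):
        cfg = tiny_config(image_px=16, patch_px=8, n_bands=2, embed_dim=8, n_heads=2, depth=1)
        m = SpectralSpatialTransformer(cfg)
        x = np.random.default_rng(0).random((2, 16, 16, 2))
        path = str(tmp_path / "model.npz")
        m.save(path)
        back = SpectralSpatialTransformer.load(path)
        assert back.cfg == cfg
        np.testing.assert_array_equal(back.predict_proba(x), m.predict_proba(x))

    def test_external_weight_import_validates(self):
        m = SpectralSpatialTransformer(
            tiny_config(image_px=16, patch_px=8, n_bands=2, embed_dim=8, n_heads=2, depth=1)
        )
        with pytest.raises(KeyError):
            m.load_external_weights({"nonexistent": np.zeros(3)})
        with pytest.raises(ValueError, match="shape"):
            m.load_external_weights({"cls_token": np.zeros(3)})
        m.load_external_weights({"cls_token": np.ones(8)})
        np.testing.assert_array_equal(m.params["cls_token"], 1.0)
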