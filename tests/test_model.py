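"""Model forward pass: attention, encoder stack, pooling, scale fusion."""

import numpy as np
import pytest

import scaleformer as sf
from scaleformer.model import (
    init_parameters,
    self_attention,
    sinusoidal_positions,
    transformer_encode,
)


def loop_attention(x, wq, bq, wk, bk, wv, bv, wo, bo, scale):
    """Independent single-head attention written with explicit loops."""
    n, e = x.shape
    q = np.array([x[i] @ wq + bq for i in range(n)])
    k = np.array([x[i] @ wk + bk for i in range(n)])
    v = np.array([x[i] @ wv + bv for i in range(n)])
    out = np.zeros((n, e))
    for i in range(n):
        logits = np.array([q[i] @ k[j] for j in range(n)])
        if scale:
            logits = logits / np.sqrt(e)
        w = np.exp(logits - logits.max())
        w = w / w.sum()
        ctx = np.zeros(e)
        for j in range(n):
            ctx += w[j] * v[j]
        out[i] = ctx @ wo + bo
    return out


def single_head_params(rng, e=4):
    p = {}
    for name in ("Wq", "Wk", "Wv", "Wo"):
        p[f"attn.{name}"] = rng.normal(size=(e, e))
    for name in ("bq", "bk", "bv", "bo"):
        p[f"attn.{name}"] = rng.normal(size=e)
    return p


class TestSelfAttention:
    @pytest.mark.parametrize("scaling", [True, False], ids=["scaled", "unscaled"])
    def test_matches_loop_oracle(self, rng, scaling):
        x = rng.normal(size=(3, 4))
        p = single_head_params(rng)
        got = self_attention(x, p, heads=1, scaling=scaling)
        want = loop_attention(
            x,
            p["attn.Wq"], p["attn.bq"], p["attn.Wk"], p["attn.bk"],
            p["attn.Wv"], p["attn.bv"], p["attn.Wo"], p["attn.bo"],
            scale=scaling,
        )
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_single_input_attends_fully_to_itself(self, rng):
        x = rng.normal(size=(1, 4))
        p = single_head_params(rng)
        got = self_attention(x, p, heads=1)
        want = (x @ p["attn.Wv"] + p["attn.bv"]) @ p["attn.Wo"] + p["attn.bo"]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_multi_head_agrees_with_per_head_loop(self, rng):
        e, heads = 8, 2
        x = rng.normal(size=(5, e))
        p = {}
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"attn.{name}"] = rng.normal(size=(e, e))
        for name in ("bq", "bk", "bv", "bo"):
            p[f"attn.{name}"] = rng.normal(size=e)
        got = self_attention(x, p, heads=heads)
        # reference: run each head's slice separately, concat, then project
        dh = e // heads
        q = x @ p["attn.Wq"] + p["attn.bq"]
        k = x @ p["attn.Wk"] + p["attn.bk"]
        v = x @ p["attn.Wv"] + p["attn.bv"]
        chunks = []
        for h in range(heads):
            sl = slice(h * dh, (h + 1) * dh)
            logits = q[:, sl] @ k[:, sl].T / np.sqrt(dh)
            w = np.exp(logits - logits.max(axis=1, keepdims=True))
            w = w / w.sum(axis=1, keepdims=True)
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)
            chunks.append(w @ v[:, sl])
        want = np.concatenate(chunks, axis=1) @ p["attn.Wo"] + p["attn.bo"]
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestTransformerEncode:
    @pytest.mark.parametrize("n", [1, 25, 49, 81])
    def test_shape_preserved(self, rng, n):
        cfg = sf.TransformerConfig(layers=2, heads=4, ffn_width=32, e=16)
        params = {}
        from scaleformer.model import _init_transformer

        _init_transformer(params, "", cfg, rng)
        out = transformer_encode(rng.normal(size=(n, 16)), params, cfg)
        assert out.shape == (n, 16)
        assert np.all(np.isfinite(out))

    def test_permutation_equivariant_without_positions(self, rng):
        from scaleformer.model import _init_transformer

        cfg = sf.TransformerConfig(layers=2, heads=2, ffn_width=32, e=16)
        params = {}
        _init_transformer(params, "", cfg, rng)
        x = rng.normal(size=(9, 16))
        perm = rng.permutation(9)
        out = transformer_encode(x, params, cfg)
        out_perm = transformer_encode(x[perm], params, cfg)
        np.testing.assert_allclose(out[perm], out_perm, atol=1e-5)

    def test_zeroed_output_projections_reduce_to_layer_norm(self, rng):
        from scaleformer.model import _init_transformer, _layer_norm
        from scaleformer.autodiff import Tensor

        cfg = sf.TransformerConfig(layers=2, heads=2, ffn_width=32, e=16)
        params = {}
        _init_transformer(params, "", cfg, rng)
        for key in list(params):
            if key.endswith(("attn.Wo", "attn.bo", "ffn.W2", "ffn.b2")):
                params[key] = np.zeros_like(params[key])
        x = rng.normal(size=(5, 16))
        out = transformer_encode(x, params, cfg)
        want = _layer_norm(
            Tensor(x), Tensor(params["ln_f.g"]), Tensor(params["ln_f.b"])
        ).data
        np.testing.assert_allclose(out, want, atol=1e-12)


class TestContextualizePatches:
    @pytest.fixture()
    def model(self):
        cfg = sf.ModelConfig(embed_dim=16, heads=2, ffn_width=32, native_dim=8)
        return sf.ScaleAwareModel(cfg, seed=0)

    def test_pooled_invariant_to_permutation_with_positions_off(self, model, rng):
        pe = rng.normal(size=(25, 16))
        _, pooled = model.contextualize_patches(pe, use_positions=False)
        _, pooled_perm = model.contextualize_patches(
            pe[rng.permutation(25)], use_positions=False
        )
        np.testing.assert_allclose(pooled, pooled_perm, atol=1e-5)

    def test_pooled_sensitive_to_permutation_with_positions_on(self, model, rng):
        pe = rng.normal(size=(25, 16))
        perm = rng.permutation(25)
        _, pooled = model.contextualize_patches(pe, use_positions=True)
        _, pooled_perm = model.contextualize_patches(pe[perm], use_positions=True)
        assert np.abs(pooled - pooled_perm).max() > 1e-4

    def test_pooled_is_row_mean_of_contextualized(self, model, rng):
        cpe, pooled = model.contextualize_patches(rng.normal(size=(9, 16)))
        np.testing.assert_allclose(pooled, cpe.mean(axis=0), atol=1e-6)

    def test_pooled_width_is_embed_dim_at_defaults(self, rng):
        model = sf.ScaleAwareModel(sf.ModelConfig(native_dim=8), seed=0)
        _, pooled = model.contextualize_patches(rng.normal(size=(25, 128)))
        assert pooled.shape == (128,)


class TestFuseScales:
    def test_default_shapes(self, rng):
        model = sf.ScaleAwareModel(sf.ModelConfig(native_dim=8), seed=0)
        pooled = [rng.normal(size=128) for _ in range(3)]
        scores = model.fuse_scales(pooled)
        assert scores.shape == (4,)
        assert model.params["cls.W"].shape == (384, 4)

    def test_single_scale_degenerate_case(self, rng):
        cfg = sf.ModelConfig(
            embed_dim=16, heads=2, ffn_width=32, native_dim=8,
            scales=("10x",), m_per_scale={"10x": 9},
        )
        model = sf.ScaleAwareModel(cfg, seed=0)
        scores = model.fuse_scales([rng.normal(size=16)])
        assert scores.shape == (4,) and np.all(np.isfinite(scores))

    def test_swapping_scales_changes_scores(self, rng):
        cfg = sf.ModelConfig(embed_dim=16, heads=2, ffn_width=32, native_dim=8)
        model = sf.ScaleAwareModel(cfg, seed=0)
        a, b, c = (rng.normal(size=16) for _ in range(3))
        assert not np.allclose(model.params["pse"][0], model.params["pse"][1])
        assert np.abs(
            model.fuse_scales([a, b, c]) - model.fuse_scales([b, a, c])
        ).max() > 1e-8

    def test_zero_scales_rejected(self):
        model = sf.ScaleAwareModel(sf.ModelConfig(native_dim=8), seed=0)
        with pytest.raises(ValueError):
            model.fuse_scales([])


class TestEmbedPatches:
    def test_identical_patches_identical_rows_and_pure_function(self, backbone):
        cfg = sf.ModelConfig(embed_dim=32, heads=2, ffn_width=32, native_dim=192)
        model = sf.ScaleAwareModel(cfg, seed=0)
        patch = np.full((20, 20, 3), 128, dtype=np.uint8)
        grid = sf.PatchGrid(np.stack([patch] * 4), (2, 2), "10x")
        pe = model.embed_patches(grid, backbone)
        assert pe.shape == (4, 32)
        np.testing.assert_array_equal(pe[0], pe[1])
        np.testing.assert_array_equal(pe, model.embed_patches(grid, backbone))

    def test_patch_permutation_permutes_rows(self, backbone, rng):
        cfg = sf.ModelConfig(embed_dim=32, heads=2, ffn_width=32, native_dim=192)
        model = sf.ScaleAwareModel(cfg, seed=0)
        patches = rng.integers(0, 255, (4, 16, 16, 3)).astype(np.uint8)
        perm = np.array([2, 0, 3, 1])
        pe = model.embed_patches(sf.PatchGrid(patches, (2, 2), "10x"), backbone)
        pe_perm = model.embed_patches(sf.PatchGrid(patches[perm], (2, 2), "10x"), backbone)
        np.testing.assert_allclose(pe[perm], pe_perm, atol=1e-12)


def test_sinusoidal_positions_are_bounded_and_distinct():
    pos = sinusoidal_positions(81, 128)
    assert pos.shape == (81, 128)
    assert np.abs(pos).max() <= 1.0
    assert np.unique(pos, axis=0).shape[0] == 81


def test_forward_finite_on_finite_input(rng):
    cfg = sf.ModelConfig(embed_dim=16, heads=2, ffn_width=32, native_dim=8)
    model = sf.ScaleAwareModel(cfg, seed=1)
    emb = {t: rng.normal(size=(cfg.m_per_scale[t], 8)) * 100 for t in cfg.scales}
    scores = model.forward(emb).data
    assert np.all(np.isfinite(scores))


def test_checkpoint_roundtrip(tmp_path, rng):
    cfg = sf.ModelConfig(embed_dim=16, heads=2, ffn_width=32, native_dim=8)
    model = sf.ScaleAwareModel(cfg, seed=5)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = sf.ScaleAwareModel.load(path)
    assert loaded.cfg == cfg
    emb = {t: rng.normal(size=(cfg.m_per_scale[t], 8)) for t in cfg.scales}
    np.testing.assert_array_equal(model.forward(emb).data, loaded.forward(emb).data)
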