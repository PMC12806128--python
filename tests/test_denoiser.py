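"""Architecture unit oracles: attention, AdaLN, adapters, gradients, variants."""

import numpy as np
import pytest

from perturbdiff.autodiff import Tensor
from perturbdiff.denoiser import (
    AdaDiTLayer,
    CatCrossDiTLayer,
    CatOnlyCrossDiTLayer,
    CrossDiTLayer,
    Denoiser,
    DenoiserConfig,
    MultiHeadAttention,
    adaln_modulate,
    sinusoidal_embedding,
)
from perturbdiff.diffusion import diffusion_loss

RNG = lambda s=0: np.random.default_rng(s)


def small_config(variant="catcrossdit", **kw):
    defaults = dict(
        n_gene=6, d_model=8, n_layers=2, n_heads=2, d_text=5, max_tokens=3,
        pert_input="text_pooled" if variant == "adadit" else "text_tokens", ffn_mult=2,
    )
    defaults.update(kw)
    return DenoiserConfig(variant=variant, **defaults)


def pert_for(cfg, B, rng):
    if cfg.variant == "adadit":
        return rng.normal(size=(B, cfg.d_text))
    return rng.normal(size=(B, cfg.max_tokens, cfg.d_text)), np.ones((B, cfg.max_tokens), bool)


def zero_sublayers(module):
    """Zero every attention / feed-forward / modulation weight, keeping
    layer-norm gains: the residual path must then be the identity."""
    for layer in module.layers if isinstance(module, Denoiser) else [module]:
        for name, sub in vars(layer).items():
            if isinstance(sub, MultiHeadAttention):
                for lin in (sub.wq, sub.wk, sub.wv, sub.wo):
                    lin.W.data[:] = 0
                    lin.b.data[:] = 0
            elif name == "ffn":
                for lin in (sub.fc1, sub.fc2):
                    lin.W.data[:] = 0
                    lin.b.data[:] = 0
            elif name.startswith(("head_", "mlp_")):
                sub.W.data[:] = 0
                sub.b.data[:] = 0


class TestTimestepEmbedding:
    def test_zero_timestep_sinusoid(self):
        enc = sinusoidal_embedding(0, 8)[0]
        assert np.allclose(enc[:4], 0.0)
        assert np.allclose(enc[4:], 1.0)

    def test_distinct_timesteps_differ(self):
        assert not np.allclose(sinusoidal_embedding(1, 16), sinusoidal_embedding(2, 16))

    def test_deterministic_through_mlp(self):
        cfg = small_config()
        m = Denoiser(cfg, seed=0)
        a = m.t_embed(np.array([3.0])).data
        b = m.t_embed(np.array([3.0])).data
        assert np.array_equal(a, b)


class TestAttention:
    def test_single_context_token_returns_its_value_projection(self):
        rng = RNG(1)
        attn = MultiHeadAttention(8, 2, rng)
        x = Tensor(rng.normal(size=(1, 4, 8)))
        ctx_vec = rng.normal(size=8)
        ctx = Tensor(ctx_vec[None, None, :])
        out = attn(x, ctx).data
        expected = (ctx_vec @ attn.wv.W.data + attn.wv.b.data) @ attn.wo.W.data + attn.wo.b.data
        for q in range(4):
            assert np.allclose(out[0, q], expected, atol=1e-10)

    def test_identical_keys_average_value_projections(self):
        rng = RNG(2)
        attn = MultiHeadAttention(4, 1, rng)
        attn.wk.W.data[:] = 0.0  # all keys equal -> uniform softmax
        attn.wk.b.data[:] = 0.0
        x = Tensor(rng.normal(size=(1, 2, 4)))
        ctx_tokens = rng.normal(size=(1, 3, 4))
        out = attn(x, Tensor(ctx_tokens)).data
        v = ctx_tokens[0] @ attn.wv.W.data + attn.wv.b.data
        expected = v.mean(axis=0) @ attn.wo.W.data + attn.wo.b.data
        assert np.allclose(out[0, 0], expected, atol=1e-10)
        assert np.allclose(out[0, 1], expected, atol=1e-10)

    def test_hand_computed_softmax_mixture(self):
        # 1 head, d_model=2, identity projections: attention reduces to
        # softmax(q.k/sqrt(2)) mixing of the context rows
        attn = MultiHeadAttention(2, 1, RNG(0))
        for lin in (attn.wq, attn.wk, attn.wv, attn.wo):
            lin.W.data = np.eye(2)
            lin.b.data[:] = 0
        q = np.array([[1.0, 0.0]])
        ctx = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = attn(Tensor(q[None]), Tensor(ctx[None])).data[0, 0]
        logits = ctx @ q[0] / np.sqrt(2)
        w = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(out, w @ ctx, atol=1e-12)

    def test_self_attention_permutation_equivariance(self):
        rng = RNG(3)
        attn = MultiHeadAttention(8, 2, rng)
        tokens = rng.normal(size=(1, 5, 8))
        out = attn(Tensor(tokens), Tensor(tokens)).data
        perm = rng.permutation(5)
        out_p = attn(Tensor(tokens[:, perm]), Tensor(tokens[:, perm])).data
        assert np.allclose(out[:, perm], out_p, atol=1e-10)

    def test_fully_masked_context_raises(self):
        attn = MultiHeadAttention(4, 1, RNG(0))
        x = Tensor(np.zeros((1, 2, 4)))
        ctx = Tensor(np.zeros((1, 3, 4)))
        with pytest.raises(ValueError, match="mask"):
            attn(x, ctx, mask=np.zeros((1, 3), dtype=bool))

    def test_masked_tokens_do_not_influence_output(self):
        rng = RNG(4)
        attn = MultiHeadAttention(4, 2, rng)
        x = Tensor(rng.normal(size=(1, 2, 4)))
        ctx = rng.normal(size=(1, 3, 4))
        mask = np.array([[True, True, False]])
        out1 = attn(x, Tensor(ctx), mask).data
        ctx2 = ctx.copy()
        ctx2[0, 2] = 99.0  # change only the masked token
        out2 = attn(x, Tensor(ctx2), mask).data
        assert np.allclose(out1, out2, atol=1e-9)


class TestAdaLN:
    def test_neutral_modulation_is_identity(self):
        x = RNG(0).normal(size=(2, 3, 4))
        out = adaln_modulate(Tensor(x), np.ones(4), np.zeros(4)).data
        assert np.allclose(out, x)

    def test_closed_gate_zeroes_output(self):
        x = RNG(0).normal(size=(2, 3, 4))
        out = adaln_modulate(Tensor(x), np.zeros(4), stage="gate").data
        assert np.allclose(out, 0.0)

    def test_hand_scale_shift(self):
        out = adaln_modulate(Tensor(np.array([[0.5]])), np.array([2.0]), np.array([1.0])).data
        assert np.allclose(out, [[2.0]])

    def test_width_mismatch_raises(self):
        with pytest.raises(ValueError):
            adaln_modulate(Tensor(np.zeros((1, 2, 4))), np.ones(3), np.zeros(3))


class TestLayersAndVariants:
    @pytest.mark.parametrize("variant", ["crossdit", "catcrossdit", "adadit", "catonlycrossdit"])
    def test_zero_sublayer_weights_give_residual_identity(self, variant):
        cfg = small_config(variant)
        rng = RNG(5)
        layer = {
            "crossdit": CrossDiTLayer,
            "catcrossdit": CatCrossDiTLayer,
            "adadit": AdaDiTLayer,
            "catonlycrossdit": CatOnlyCrossDiTLayer,
        }[variant](cfg, rng)
        zero_sublayers(layer)
        x = Tensor(rng.normal(size=(2, cfg.n_gene, cfg.d_model)))
        if variant == "crossdit":
            ctx = Tensor(rng.normal(size=(2, cfg.n_gene, cfg.d_model)))
            pert = Tensor(rng.normal(size=(2, 3, cfg.d_model)))
            out = layer(x, ctx, pert, np.ones((2, 3), bool))
        elif variant == "adadit":
            out = layer(x, Tensor(rng.normal(size=(2, cfg.d_model))))
        else:
            pert = Tensor(rng.normal(size=(2, 3, cfg.d_model)))
            out = layer(x, pert, np.ones((2, 3), bool))
        assert np.allclose(out.data, x.data, atol=1e-12)

    def test_adadit_identity_modulation_passes_through(self):
        # gamma=1, beta=0, alpha=0 makes each block contribute nothing
        cfg = small_config("adadit")
        layer = AdaDiTLayer(cfg, RNG(0))
        # freshly built layers have exactly this modulation (zero-init heads)
        x = Tensor(RNG(1).normal(size=(1, cfg.n_gene, cfg.d_model)))
        out = layer(x, Tensor(np.zeros((1, cfg.d_model))))
        assert np.allclose(out.data, x.data, atol=1e-12)

    @pytest.mark.parametrize("variant", ["crossdit", "catcrossdit", "adadit", "catonlycrossdit"])
    def test_predict_shape_and_determinism(self, variant):
        cfg = small_config(variant)
        m = Denoiser(cfg, seed=7)
        rng = RNG(8)
        x_t = rng.normal(size=(3, cfg.n_gene))
        c_pre = rng.normal(size=(3, cfg.n_gene))
        pert = pert_for(cfg, 3, rng)
        a = m.predict(x_t, np.array([1, 2, 3]), c_pre, pert)
        b = m.predict(x_t, np.array([1, 2, 3]), c_pre, pert)
        assert a.shape == (3, cfg.n_gene)
        assert np.array_equal(a, b)

    def test_single_vector_input_round_trip(self):
        cfg = small_config()
        m = Denoiser(cfg, seed=0)
        rng = RNG(0)
        out = m.predict(rng.normal(size=cfg.n_gene), 1, rng.normal(size=cfg.n_gene),
                        (rng.normal(size=(cfg.max_tokens, cfg.d_text)), np.ones(cfg.max_tokens, bool)))
        assert out.shape == (cfg.n_gene,)

    def test_gene_permutation_consistency(self):
        # permuting genes together with Pos rows permutes the output identically
        cfg = small_config("catcrossdit")
        m = Denoiser(cfg, seed=3)
        rng = RNG(9)
        x_t = rng.normal(size=(2, cfg.n_gene))
        c_pre = rng.normal(size=(2, cfg.n_gene))
        pert = pert_for(cfg, 2, rng)
        base = m.predict(x_t, 2, c_pre, pert)
        perm = rng.permutation(cfg.n_gene)
        m.pos.data = m.pos.data[perm]
        permuted = m.predict(x_t[:, perm], 2, c_pre[:, perm], pert)
        assert np.allclose(base[:, perm], permuted, atol=1e-8)

    def test_catonly_variant_has_no_cross_gene_flow(self):
        # without self-attention, changing one gene's control affects only
        # that gene's output
        cfg = small_config("catonlycrossdit")
        m = Denoiser(cfg, seed=4)
        rng = RNG(10)
        x_t = rng.normal(size=(1, cfg.n_gene))
        c_pre = rng.normal(size=(1, cfg.n_gene))
        pert = pert_for(cfg, 1, rng)
        base = m.predict(x_t, 1, c_pre, pert)
        c_mod = c_pre.copy()
        c_mod[0, 2] += 1.0
        out = m.predict(x_t, 1, c_mod, pert)
        changed = ~np.isclose(base[0], out[0], atol=1e-9)
        assert changed[2]
        assert not changed[[0, 1, 3, 4, 5]].any()

    @pytest.mark.parametrize("variant", ["crossdit", "catcrossdit", "adadit", "catonlycrossdit"])
    def test_each_condition_influences_output(self, variant):
        cfg = small_config(variant)
        m = Denoiser(cfg, seed=6)
        rng = RNG(11)
        x_t = rng.normal(size=(1, cfg.n_gene))
        c_pre = rng.normal(size=(1, cfg.n_gene))
        pert = pert_for(cfg, 1, rng)
        base = m.predict(x_t, 1, c_pre, pert)
        assert not np.allclose(base, m.predict(x_t, 1, c_pre + 0.5, pert))
        if variant == "adadit":
            # modulation heads are zero-initialized, so nudge them so the
            # perturbation path is live before the ablation probe
            for layer in m.layers:
                layer.head_a1.W.data[:] = 0.1
            pert2 = pert + 0.5
        else:
            pert2 = (pert[0] + 0.5, pert[1])
        assert not np.allclose(base, m.predict(x_t, 1, c_pre, pert2))


class TestAdapters:
    def test_adapter_output_shapes(self):
        cfg = small_config("catcrossdit")
        m = Denoiser(cfg, seed=0)
        rng = RNG(0)
        x_tokens, c_tokens, pert_stream, pert_mask = m.adapt_inputs(
            rng.normal(size=(3, cfg.n_gene)), 2, rng.normal(size=(3, cfg.n_gene)),
            pert_for(cfg, 3, rng),
        )
        assert x_tokens.shape == (3, cfg.n_gene, cfg.d_model)
        assert c_tokens is None  # concatenated variant has a single stream
        assert pert_stream.shape == (3, cfg.max_tokens, cfg.d_model)
        assert pert_mask.shape == (3, cfg.max_tokens)

    def test_crossdit_has_two_transcriptome_streams(self):
        cfg = small_config("crossdit")
        m = Denoiser(cfg, seed=0)
        rng = RNG(1)
        x_tokens, c_tokens, _, _ = m.adapt_inputs(
            rng.normal(size=(2, cfg.n_gene)), 1, rng.normal(size=(2, cfg.n_gene)),
            pert_for(cfg, 2, rng),
        )
        assert c_tokens is not None
        assert c_tokens.shape == x_tokens.shape

    def test_zero_adapters_give_zero_tokens(self):
        # linearity: zero weights, zero Pos and a zero timestep embedding
        # produce all-zero token streams
        cfg = small_config("catcrossdit")
        m = Denoiser(cfg, seed=0)
        for lin in (m.trans_adapter, m.pert_adapter, m.t_embed.fc1, m.t_embed.fc2):
            lin.W.data[:] = 0
            lin.b.data[:] = 0
        m.pos.data[:] = 0
        rng = RNG(2)
        x_tokens, _, pert_stream, _ = m.adapt_inputs(
            rng.normal(size=(1, cfg.n_gene)), 5, rng.normal(size=(1, cfg.n_gene)),
            pert_for(cfg, 1, rng),
        )
        assert np.allclose(x_tokens.data, 0.0)
        assert np.allclose(pert_stream.data, 0.0)


class TestGradients:
    @pytest.mark.parametrize("variant", ["crossdit", "catcrossdit", "adadit", "catonlycrossdit"])
    def test_finite_difference_gradcheck_four_gene_toy(self, variant):
        cfg = small_config(
            variant, n_gene=4, d_model=4, n_layers=1, n_heads=2, d_text=3, max_tokens=2
        )
        m = Denoiser(cfg, seed=12)
        # make zero-initialized modulation paths live so their grads are probed
        if variant == "adadit":
            for layer in m.layers:
                for h in (layer.head_g1, layer.head_b1, layer.head_a1,
                          layer.head_g2, layer.head_b2, layer.head_a2):
                    h.W.data = RNG(13).normal(scale=0.3, size=h.W.data.shape)
        rng = RNG(14)
        x_t = rng.normal(size=(2, 4))
        c_pre = rng.normal(size=(2, 4))
        pert = pert_for(cfg, 2, rng)
        eps_true = rng.normal(size=(2, 4))

        def loss_value():
            return diffusion_loss(m.forward(x_t, np.array([1, 2]), c_pre, pert), Tensor(eps_true))

        loss = loss_value()
        loss.backward()
        rng_pick = RNG(15)
        for p in m.parameters():
            flat = p.data.reshape(-1)
            gflat = p.grad.reshape(-1) if p.grad is not None else np.zeros_like(flat)
            for j in rng_pick.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[j]
                h = 1e-5
                flat[j] = old + h
                f1 = float(loss_value().data)
                flat[j] = old - h
                f2 = float(loss_value().data)
                flat[j] = old
                num = (f1 - f2) / (2 * h)
                assert num == pytest.approx(gflat[j], rel=1e-4, abs=1e-7)

    def test_tiny_network_overfits_single_pair(self):
        # training on one fixed (x_t, eps) pair drives the loss toward zero
        from perturbdiff.autodiff import AdamW

        cfg = small_config("catcrossdit", n_gene=8, d_model=16, n_layers=2, n_heads=2)
        m = Denoiser(cfg, seed=1)
        rng = RNG(2)
        x_t = rng.normal(size=(1, 8))
        c_pre = rng.normal(size=(1, 8))
        pert = pert_for(cfg, 1, rng)
        eps = rng.normal(size=(1, 8))
        opt = AdamW(m.parameters(), lr=5e-3)
        first = None
        for _ in range(150):
            loss = diffusion_loss(m.forward(x_t, 3, c_pre, pert), Tensor(eps))
            if first is None:
                first = float(loss.data)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert float(loss.data) < 0.02 * first


class TestConfigValidation:
    def test_head_divisibility(self):
        with pytest.raises(ValueError):
            small_config(d_model=10, n_heads=4)

    def test_adadit_requires_vector_input(self):
        with pytest.raises(ValueError):
            DenoiserConfig(variant="adadit", n_gene=4, pert_input="text_tokens")

    def test_token_variants_require_tokens(self):
        with pytest.raises(ValueError):
            DenoiserConfig(variant="crossdit", n_gene=4, pert_input="text_pooled")

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            DenoiserConfig(variant="mlp", n_gene=4)
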