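"""Noise-predictor networks eps_theta(x_t, t | c_pre, c_pert).

Four transformer-layer variants differ in how the two conditions are fused
into the noisy transcriptome stream:

- ``crossdit``     — x_t and c_pre are adapted to separate token streams; each
  layer cross-attends x_t tokens to c_pre tokens, then to perturbation tokens,
  then applies a feed-forward block (all pre-norm residual).
- ``catcrossdit``  — x_t and c_pre are concatenated per gene into one token
  stream; each layer runs self-attention, cross-attention to perturbation
  tokens, and feed-forward.
- ``catonlycrossdit`` — like catcrossdit but without self-attention.
- ``adadit``       — like catcrossdit but the perturbation enters as a pooled
  vector through adaptive layer norm (scale/shift before, gate after the
  self-attention and feed-forward blocks) instead of cross-attention.

Shared plumbing: three linear adapters (transcriptome, perturbation,
timestep), a learnable per-gene positional table ``Pos`` added to
transcriptome tokens, the timestep embedding added to every stream, and a
per-token linear output head after a final layer norm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Module, Parameter, Tensor, no_grad

__all__ = [
    "DenoiserConfig",
    "Denoiser",
    "sinusoidal_embedding",
    "timestep_embed",
    "adaln_modulate",
    "cross_attention",
    "self_attention",
    "predict_noise",
]

VARIANTS = ("crossdit", "catcrossdit", "adadit", "catonlycrossdit")
TOKEN_PERT_INPUTS = ("text_tokens",)
VECTOR_PERT_INPUTS = ("text_pooled", "fingerprint")


@dataclass
class DenoiserConfig:
    """Architecture hyperparameters for the noise predictor."""

    variant: str
    n_gene: int
    d_model: int = 128
    n_layers: int = 4
    n_heads: int = 4
    d_text: int = 64
    max_tokens: int = 32
    pert_input: str = "text_tokens"
    ffn_mult: int = 4

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.variant == "adadit":
            if self.pert_input not in VECTOR_PERT_INPUTS:
                raise ValueError("adadit requires a vector-like pert_input (pooled/fingerprint)")
        elif self.pert_input not in TOKEN_PERT_INPUTS:
            raise ValueError(f"{self.variant} requires pert_input='text_tokens'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DenoiserConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, zero: bool = False):
        if zero:
            w = np.zeros((d_in, d_out))
        else:
            w = rng.normal(scale=1.0 / math.sqrt(d_in), size=(d_in, d_out))
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        # flatten leading axes so BLAS sees one large GEMM instead of a
        # batch of tiny ones
        if x.ndim > 2:
            lead = x.shape[:-1]
            flat = x.reshape(-1, x.shape[-1]) @ self.W + self.b
            return flat.reshape(*lead, self.W.shape[-1])
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gain = Parameter(np.ones(d))
        self.bias = Parameter(np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm() * self.gain + self.bias


class FeedForward(Module):
    def __init__(self, d_model: int, mult: int, rng):
        self.fc1 = Linear(d_model, mult * d_model, rng)
        self.fc2 = Linear(mult * d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class MultiHeadAttention(Module):
    """Standard multi-head scaled-dot-product attention.

    Queries come from ``x``; keys and values from ``context`` (pass the same
    tensor for self-attention).  ``mask`` is a boolean (batch, n_context)
    array marking valid context tokens.
    """

    def __init__(self, d_model: int, n_heads: int, rng):
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, B: int, N: int) -> Tensor:
        return x.reshape(B, N, self.n_heads, self.d_head).swapaxes(1, 2)

    def __call__(self, x: Tensor, context: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, Nq, D = x.shape
        Nk = context.shape[1]
        q = self._split(self.wq(x), B, Nq)
        k = self._split(self.wk(context), B, Nk)
        v = self._split(self.wv(context), B, Nk)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_head))
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.ndim == 1:
                mask = mask[None, :]
            if not mask.any(axis=-1).all():
                raise ValueError("attention mask leaves no valid context token for some row")
            bias = np.where(mask, 0.0, -1e9)[:, None, None, :]
            scores = scores + bias
        attn = scores.softmax()
        out = (attn @ v).swapaxes(1, 2).reshape(B, Nq, D)
        return self.wo(out)


def sinusoidal_embedding(t, d: int) -> np.ndarray:
    """Fixed sine/cosine encoding of (batched) timesteps, shape (..., d)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = d // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    angles = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(angles), np.cos(angles)], axis=-1)
    if emb.shape[-1] < d:  # odd d: pad with one zero column
        emb = np.concatenate([emb, np.zeros((emb.shape[0], d - emb.shape[-1]))], axis=-1)
    return emb


class TimestepEmbedder(Module):
    """Sinusoidal encoding followed by a two-layer MLP to d_model."""

    def __init__(self, d_model: int, rng):
        self.d_model = d_model
        self.fc1 = Linear(d_model, d_model, rng)
        self.fc2 = Linear(d_model, d_model, rng)

    def __call__(self, t) -> Tensor:
        enc = Tensor(sinusoidal_embedding(t, self.d_model))
        return self.fc2(self.fc1(enc).gelu())


def timestep_embed(t, d_model: int, rng_or_module=None) -> np.ndarray:
    """Functional form of the timestep adapter (fresh weights unless a module
    is supplied); mainly a convenience for inspection and tests."""
    if isinstance(rng_or_module, TimestepEmbedder):
        return rng_or_module(t).data
    rng = rng_or_module if isinstance(rng_or_module, np.random.Generator) else np.random.default_rng(0)
    return TimestepEmbedder(d_model, rng)(t).data


def adaln_modulate(x: Tensor | np.ndarray, gamma, beta=None, alpha=None, stage: str = "scale_shift"):
    """Adaptive layer-norm modulation: scale/shift ``gamma*x + beta`` or gate
    ``alpha*x``; parameter vectors broadcast over token positions."""
    x = Tensor.as_tensor(x)
    d = x.shape[-1]

    def _prep(v):
        v = Tensor.as_tensor(v)
        if v.shape[-1] != d:
            raise ValueError(f"modulation width {v.shape[-1]} != feature width {d}")
        if v.ndim == 2 and x.ndim == 3:  # (B, d) against (B, N, d)
            v = v.reshape(v.shape[0], 1, d)
        return v

    if stage == "scale_shift":
        if beta is None:
            raise ValueError("scale_shift stage needs beta")
        return x * _prep(gamma) + _prep(beta)
    if stage == "gate":
        gate = gamma if alpha is None else alpha
        return x * _prep(gate)
    raise ValueError(f"unknown stage {stage!r}")


def cross_attention(x_tokens, c_tokens, mask=None, *, module: MultiHeadAttention) -> np.ndarray:
    """Apply a built attention module to raw arrays (evaluation helper)."""
    out = module(Tensor.as_tensor(x_tokens), Tensor.as_tensor(c_tokens), mask)
    return out.data


def self_attention(x_tokens, *, module: MultiHeadAttention) -> np.ndarray:
    """Self-attention is cross-attention with the context set to the input."""
    return cross_attention(x_tokens, x_tokens, module=module)


# ---------------------------------------------------------------------------
# transformer layers
# ---------------------------------------------------------------------------


class CrossDiTLayer(Module):
    def __init__(self, cfg: DenoiserConfig, rng):
        self.ln_pre = LayerNorm(cfg.d_model)
        self.attn_pre = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ln_pert = LayerNorm(cfg.d_model)
        self.attn_pert = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ln_ffn = LayerNorm(cfg.d_model)
        self.ffn = FeedForward(cfg.d_model, cfg.ffn_mult, rng)

    def __call__(self, x, cpre_tokens, pert_tokens, pert_mask):
        x = x + self.attn_pre(self.ln_pre(x), cpre_tokens)
        x = x + self.attn_pert(self.ln_pert(x), pert_tokens, pert_mask)
        x = x + self.ffn(self.ln_ffn(x))
        return x


class CatCrossDiTLayer(Module):
    def __init__(self, cfg: DenoiserConfig, rng):
        self.ln_self = LayerNorm(cfg.d_model)
        self.attn_self = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ln_pert = LayerNorm(cfg.d_model)
        self.attn_pert = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ln_ffn = LayerNorm(cfg.d_model)
        self.ffn = FeedForward(cfg.d_model, cfg.ffn_mult, rng)

    def __call__(self, x, pert_tokens, pert_mask):
        h = self.ln_self(x)
        x = x + self.attn_self(h, h)
        x = x + self.attn_pert(self.ln_pert(x), pert_tokens, pert_mask)
        x = x + self.ffn(self.ln_ffn(x))
        return x


class CatOnlyCrossDiTLayer(Module):
    def __init__(self, cfg: DenoiserConfig, rng):
        self.ln_pert = LayerNorm(cfg.d_model)
        self.attn_pert = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ln_ffn = LayerNorm(cfg.d_model)
        self.ffn = FeedForward(cfg.d_model, cfg.ffn_mult, rng)

    def __call__(self, x, pert_tokens, pert_mask):
        x = x + self.attn_pert(self.ln_pert(x), pert_tokens, pert_mask)
        x = x + self.ffn(self.ln_ffn(x))
        return x


class AdaDiTLayer(Module):
    """Self-attention + feed-forward with two AdaLN modulation sets.

    The modulation MLP takes the perturbation vector and emits
    (gamma1, beta1, alpha1, gamma2, beta2, alpha2); its final layer is
    zero-initialized with bias set so that gamma=1, beta=0, alpha=0 — gates
    start closed and open during training.
    """

    def __init__(self, cfg: DenoiserConfig, rng):
        d = cfg.d_model
        self.d_model = d
        self.mlp_in = Linear(d, d, rng)
        # six modulation heads off a shared hidden layer; zero weights with
        # gamma biased to 1 so each block starts as the identity
        self.head_g1 = Linear(d, d, rng, zero=True)
        self.head_b1 = Linear(d, d, rng, zero=True)
        self.head_a1 = Linear(d, d, rng, zero=True)
        self.head_g2 = Linear(d, d, rng, zero=True)
        self.head_b2 = Linear(d, d, rng, zero=True)
        self.head_a2 = Linear(d, d, rng, zero=True)
        self.head_g1.b = Parameter(np.ones(d))
        self.head_g2.b = Parameter(np.ones(d))
        self.ln_self = LayerNorm(d)
        self.attn_self = MultiHeadAttention(d, cfg.n_heads, rng)
        self.ln_ffn = LayerNorm(d)
        self.ffn = FeedForward(d, cfg.ffn_mult, rng)

    def __call__(self, x, pert_vec):
        hidden = self.mlp_in(pert_vec).gelu()  # (B, d)
        h = adaln_modulate(self.ln_self(x), self.head_g1(hidden), self.head_b1(hidden))
        h = self.attn_self(h, h)
        x = x + adaln_modulate(h, self.head_a1(hidden), stage="gate")
        h = adaln_modulate(self.ln_ffn(x), self.head_g2(hidden), self.head_b2(hidden))
        h = self.ffn(h)
        x = x + adaln_modulate(h, self.head_a2(hidden), stage="gate")
        return x


class Denoiser(Module):
    """The full noise predictor: adapters, layer stack, output head."""

    def __init__(self, config: DenoiserConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config
        d = cfg.d_model
        self.t_embed = TimestepEmbedder(d, rng)
        if cfg.variant == "crossdit":
            self.trans_adapter_x = Linear(1, d, rng)
            self.trans_adapter_c = Linear(1, d, rng)
        else:
            self.trans_adapter = Linear(2, d, rng)
        d_pert_in = cfg.d_text
        self.pert_adapter = Linear(d_pert_in, d, rng)
        # gene positional table; initialized at unit-ish scale so per-gene
        # routing in (cross-)attention is distinguishable from the start
        self.pos = Parameter(rng.normal(scale=1.0, size=(cfg.n_gene, d)))
        # head before layers: adapter/head weights then depend only on the
        # seed, not on the layer count
        self.ln_out = LayerNorm(d)
        self.head = Linear(d, 1, rng)
        layer_cls = {
            "crossdit": CrossDiTLayer,
            "catcrossdit": CatCrossDiTLayer,
            "catonlycrossdit": CatOnlyCrossDiTLayer,
            "adadit": AdaDiTLayer,
        }[cfg.variant]
        self.layers = [layer_cls(cfg, rng) for _ in range(cfg.n_layers)]

    # -- condition adaptation ------------------------------------------------
    def _pert_stream(self, pert, t_emb: Tensor):
        cfg = self.config
        if cfg.variant == "adadit":
            vec = np.asarray(pert, dtype=np.float64)
            if vec.ndim == 1:
                vec = vec[None, :]
            if vec.shape[-1] != cfg.d_text:
                raise ValueError(f"perturbation vector width {vec.shape[-1]} != d_text {cfg.d_text}")
            return self.pert_adapter(Tensor(vec)) + t_emb, None
        tokens, mask = pert
        tokens = np.asarray(tokens, dtype=np.float64)
        mask = np.asarray(mask, dtype=bool)
        if tokens.ndim == 2:
            tokens = tokens[None]
            mask = mask[None]
        if tokens.shape[-1] != cfg.d_text:
            raise ValueError(f"perturbation token width {tokens.shape[-1]} != d_text {cfg.d_text}")
        B = tokens.shape[0]
        adapted = self.pert_adapter(Tensor(tokens)) + t_emb.reshape(B, 1, cfg.d_model)
        return adapted, mask

    def adapt_inputs(self, x_t, t, c_pre, pert):
        """Run the three adapters.

        Returns ``(x_tokens, c_tokens, pert_stream, pert_mask)``: transcriptome
        tokens (batch, n_gene, d_model) with Pos and the timestep embedding
        added; a second c_pre token stream for the crossdit variant (None
        otherwise, where x_t and c_pre are concatenated per gene); and the
        adapted perturbation tokens/vector carrying the timestep embedding.
        """
        cfg = self.config
        x_t = np.asarray(x_t, dtype=np.float64)
        c_pre = np.asarray(c_pre, dtype=np.float64)
        if x_t.ndim == 1:
            x_t, c_pre = x_t[None], c_pre[None]
        if x_t.shape != c_pre.shape or x_t.shape[1] != cfg.n_gene:
            raise ValueError(
                f"x_t {x_t.shape} / c_pre {c_pre.shape} must both be (batch, {cfg.n_gene})"
            )
        B = x_t.shape[0]
        d = cfg.d_model
        t_arr = np.broadcast_to(np.atleast_1d(np.asarray(t, dtype=np.float64)), (B,))
        t_emb = self.t_embed(t_arr)  # (B, d)
        t_tok = t_emb.reshape(B, 1, d)

        if cfg.variant == "crossdit":
            x_tokens = self.trans_adapter_x(Tensor(x_t[..., None])) + self.pos + t_tok
            c_tokens = self.trans_adapter_c(Tensor(c_pre[..., None])) + self.pos + t_tok
        else:
            pair = np.stack([x_t, c_pre], axis=-1)  # (B, G, 2)
            x_tokens = self.trans_adapter(Tensor(pair)) + self.pos + t_tok
            c_tokens = None

        pert_stream, pert_mask = self._pert_stream(pert, t_emb)
        return x_tokens, c_tokens, pert_stream, pert_mask

    def forward(self, x_t, t, c_pre, pert) -> Tensor:
        cfg = self.config
        B = 1 if np.asarray(x_t).ndim == 1 else np.asarray(x_t).shape[0]
        G = cfg.n_gene
        x_tokens, c_tokens, pert_stream, pert_mask = self.adapt_inputs(x_t, t, c_pre, pert)

        h = x_tokens
        for layer in self.layers:
            if cfg.variant == "crossdit":
                h = layer(h, c_tokens, pert_stream, pert_mask)
            elif cfg.variant == "adadit":
                h = layer(h, pert_stream)
            else:
                h = layer(h, pert_stream, pert_mask)
        out = self.head(self.ln_out(h)).reshape(B, G)
        return out

    def predict(self, x_t, t, c_pre, pert) -> np.ndarray:
        """Inference-mode forward pass returning a plain array."""
        single = np.asarray(x_t).ndim == 1
        with no_grad():
            out = self.forward(x_t, t, c_pre, pert).data
        return out[0] if single else out


def predict_noise(model: Denoiser, x_t, t, c_pre, c_pert) -> np.ndarray:
    """Functional wrapper over :meth:`Denoiser.predict`."""
    return model.predict(x_t, t, c_pre, c_pert)
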