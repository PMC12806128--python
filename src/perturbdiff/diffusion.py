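"""Multi-conditional DDPM mathematics: schedule, forward process, loss, sampling.

The generative model treats a perturbed transcriptome ``x0`` as the data to be
generated, conditioned on the paired pre-perturbation profile ``c_pre`` and a
perturbation embedding ``c_pert``.  The forward process corrupts ``x0`` with a
variance schedule ``beta_1 < ... < beta_T``; the reverse process denoises a
standard-normal draw ``x_T`` step by step using a learned noise predictor
``eps_theta(x_t, t | c_pre, c_pert)``.

Conventions
-----------
Timesteps are 1-based at this interface (``t`` in ``[1, T]``), with the
cumulative signal fraction ``alpha_bar_0 := 1`` so that the posterior noise
scale ``sigma_1`` is exactly zero and the final denoising step is
deterministic.  The training loss is the squared L2 norm of the noise residual
summed over genes (mean over a batch); a mean-per-element reduction is
available for configuration parity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NoiseSchedule",
    "make_schedule",
    "forward_diffuse",
    "diffusion_loss",
    "reverse_step",
    "sample",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Variance schedule tables for a ``T``-step diffusion chain.

    Attributes
    ----------
    T : number of diffusion steps.
    beta : per-step noise variances, strictly increasing in (0, 1).
    alpha : ``1 - beta``.
    alpha_bar : cumulative products of ``alpha`` (signal fraction kept at t).
    sigma : reverse-process posterior noise scales,
        ``sigma_t = sqrt((1 - alpha_bar_{t-1}) / (1 - alpha_bar_t) * beta_t)``
        with ``alpha_bar_0 = 1``, hence ``sigma_1 = 0``.
    """

    T: int
    beta: np.ndarray
    alpha: np.ndarray = field(repr=False)
    alpha_bar: np.ndarray = field(repr=False)
    sigma: np.ndarray = field(repr=False)

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=np.float64)
        if beta.shape != (self.T,):
            raise ValueError(f"beta must have shape ({self.T},), got {beta.shape}")
        if not (np.all(beta > 0) and np.all(beta < 1)):
            raise ValueError("all beta_t must lie in (0, 1)")
        if not np.all(np.diff(beta) > 0) and self.T > 1:
            raise ValueError("beta must be strictly increasing")

    # 1-based lookup helpers ------------------------------------------------
    def at(self, t) -> dict:
        """Schedule values at 1-based timestep(s) ``t``."""
        idx = np.asarray(t) - 1
        if np.any(idx < 0) or np.any(idx >= self.T):
            raise ValueError(f"timestep out of range [1, {self.T}]")
        return {
            "beta": self.beta[idx],
            "alpha": self.alpha[idx],
            "alpha_bar": self.alpha_bar[idx],
            "sigma": self.sigma[idx],
        }

    # serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {"T": self.T, "beta": self.beta.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSchedule":
        return _schedule_from_beta(int(d["T"]), np.asarray(d["beta"], dtype=np.float64))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path) -> "NoiseSchedule":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _schedule_from_beta(T: int, beta: np.ndarray) -> NoiseSchedule:
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    # alpha_bar_{t-1} with the alpha_bar_0 = 1 convention
    alpha_bar_prev = np.concatenate([[1.0], alpha_bar[:-1]])
    sigma = np.sqrt((1.0 - alpha_bar_prev) / (1.0 - alpha_bar) * beta)
    return NoiseSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar, sigma=sigma)


def make_schedule(
    T: int = 1000,
    beta_start: float = 1e-4,
    beta_end: float = 0.02,
    kind: str = "linear",
) -> NoiseSchedule:
    """Build a noise schedule.

    Only ``kind="linear"`` (betas linearly spaced from ``beta_start`` to
    ``beta_end``) is supported; the defaults are the standard DDPM choice.
    """
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 < beta_start < 1.0 and 0.0 < beta_end < 1.0):
        raise ValueError("beta bounds must lie in (0, 1)")
    if T > 1 and beta_start >= beta_end:
        raise ValueError("beta_start must be < beta_end (strictly increasing schedule)")
    beta = np.linspace(beta_start, beta_end, T)
    return _schedule_from_beta(T, beta)


def forward_diffuse(x0, t, eps, sched: NoiseSchedule):
    """Closed-form forward corruption: ``x_t = sqrt(ab_t) x0 + sqrt(1-ab_t) eps``.

    ``x0``/``eps`` may be single vectors or batches (leading axis); ``t`` may be
    scalar or one per batch row.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if x0.shape != eps.shape:
        raise ValueError(f"x0 shape {x0.shape} != eps shape {eps.shape}")
    ab = sched.at(t)["alpha_bar"]
    if np.ndim(ab) > 0 and x0.ndim > 1:
        ab = np.asarray(ab)[:, None]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def diffusion_loss(eps_pred, eps_true, reduction: str = "sum"):
    """Noise-prediction objective ``||eps - eps_hat||^2``.

    For batched inputs the per-sample norm is reduced over genes by ``sum``
    (default) or ``mean``, then averaged over the batch.  Works on plain
    arrays and on autodiff tensors alike.
    """
    from .autodiff import Tensor

    if isinstance(eps_pred, Tensor) or isinstance(eps_true, Tensor):
        p = Tensor.as_tensor(eps_pred)
        q = Tensor.as_tensor(eps_true)
        if p.shape != q.shape:
            raise ValueError(f"shape mismatch {p.shape} vs {q.shape}")
        d = p - q
        sq = d * d
        if reduction == "sum":
            per = sq.sum(axis=-1) if p.ndim > 1 else sq.sum()
        elif reduction == "mean":
            per = sq.mean(axis=-1) if p.ndim > 1 else sq.mean()
        else:
            raise ValueError(f"unknown reduction {reduction!r}")
        return per.mean() if p.ndim > 1 else per

    p = np.asarray(eps_pred, dtype=np.float64)
    q = np.asarray(eps_true, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {q.shape}")
    sq = (p - q) ** 2
    if reduction == "sum":
        per = sq.sum(axis=-1)
    elif reduction == "mean":
        per = sq.mean(axis=-1)
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    return float(np.mean(per))


def reverse_step(x_t, t, eps_hat, sched: NoiseSchedule, z=None):
    """One reverse-process update from ``x_t`` to ``x_{t-1}``.

    ``x_{t-1} = (x_t - beta_t / sqrt(1-ab_t) * eps_hat) / sqrt(alpha_t)
    + sigma_t z``; ``z`` is ignored at ``t = 1`` where ``sigma_1 = 0``.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    if x_t.shape != eps_hat.shape:
        raise ValueError(f"x_t shape {x_t.shape} != eps_hat shape {eps_hat.shape}")
    vals = sched.at(t)
    mean = (x_t - vals["beta"] / np.sqrt(1.0 - vals["alpha_bar"]) * eps_hat) / np.sqrt(
        vals["alpha"]
    )
    sigma = vals["sigma"]
    if sigma == 0.0 or z is None:
        if sigma != 0.0:
            raise ValueError("z noise required for t > 1 (sigma_t > 0)")
        return mean
    z = np.asarray(z, dtype=np.float64)
    if z.shape != x_t.shape:
        raise ValueError(f"z shape {z.shape} != x_t shape {x_t.shape}")
    return mean + sigma * z


def sample(predictor, c_pre, c_pert, sched: NoiseSchedule, seed: int, n_gene: int | None = None):
    """Generate a predicted post-perturbation profile by full reverse diffusion.

    Parameters
    ----------
    predictor : callable ``(x_t, t, c_pre, c_pert) -> eps_hat`` (vector in,
        vector out; batched wrappers live in :mod:`perturbdiff.pipeline`).
    c_pre : conditioning control profile; also fixes ``n_gene`` if not given.
    seed : seeds both the initial ``x_T`` draw and every per-step ``z``.
    """
    c_pre = np.asarray(c_pre, dtype=np.float64)
    if n_gene is None:
        n_gene = c_pre.shape[-1]
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_gene)
    for t in range(sched.T, 0, -1):
        try:
            eps_hat = predictor(x, t, c_pre, c_pert)
        except Exception as exc:  # re-raise with timestep context
            raise RuntimeError(f"noise predictor failed at timestep t={t}") from exc
        eps_hat = np.asarray(eps_hat, dtype=np.float64)
        if eps_hat.shape != x.shape:
            raise ValueError(f"predictor returned shape {eps_hat.shape}, expected {x.shape}")
        z = rng.standard_normal(n_gene) if t > 1 else None
        x = reverse_step(x, t, eps_hat, sched, z)
    return x
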