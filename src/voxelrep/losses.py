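"""Training objective: normalized ELBO terms plus a subspace-restricted
multi-similarity metric loss.

With b anchors, each accompanied by n_pos positives (R = 1 + n_pos
replicates per sample), patch lattice 16^3 and physical patch size a:

* reconstruction:  L_recon = (1 / (b a^3)) * sum ||x - mu_x||^2
* KL:              L_KL    = (1 / (b d))   * sum KL(N(mu_z, sigma_z^2) || N(0, 1))
* metric:          L_MS    = the multi-similarity loss over the cosine
  similarities S[j,i,k,l] of the *semantic* latent means (first d_MS
  dimensions), normalized by b (1 + n_pos)
* total:           L = L_recon + theta_KL * L_KL + theta_MS * L_MS

S is treated as a cosine *similarity* (self-similarity 1): the sign
structure of the loss — exp(-alpha (S - lambda)) for positives,
exp(+beta (S - lambda)) for negatives — rewards large S within a sample
and small S across samples, matching the original multi-similarity
formulation. No pair mining is applied; all pairs contribute.

All functions accept NumPy arrays or autodiff Tensors and return a
Tensor (use ``.item()`` for the float).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "LossConfig",
    "reconstruction_loss",
    "kl_loss",
    "similarity_tensor",
    "multi_similarity_loss",
    "batch_loss",
]

_EPS = 1e-12


@dataclass
class LossConfig:
    """Weights and metric-loss hyperparameters.

    ``alpha``/``beta`` scale the positive/negative soft weighting,
    ``margin`` (lambda) shifts the similarities; defaults follow the
    original multi-similarity loss. ``kl_direction`` selects the
    standard VAE direction KL(q || p) or the reversed KL(p || q).
    """

    theta_kl: float = 0.1
    theta_ms: float = 1.0
    alpha: float = 2.0
    beta: float = 50.0
    margin: float = 1.0
    kl_direction: str = "standard"   # 'standard' | 'reversed'

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.theta_kl < 0 or self.theta_ms < 0:
            raise ValueError("loss weights must be non-negative")
        if self.kl_direction not in ("standard", "reversed"):
            raise ValueError(f"unknown kl_direction {self.kl_direction!r}")


def reconstruction_loss(x, mu_x, size, b: int | None = None) -> Tensor:
    """Squared-error reconstruction, normalized by anchor count and
    patch volume: (1/b) * sum_i ||x_i - mu_x_i||^2 / a_i^3.

    ``x`` and ``mu_x`` are (b, R, 16, 16, 16) (or any layout with three
    trailing patch axes); ``size`` is the physical patch size a, a
    scalar or a per-patch array broadcastable to the leading axes. For
    flat (N, ...) layouts pass ``b`` explicitly.
    """
    x, mu_x = as_tensor(x), as_tensor(mu_x)
    if x.shape != mu_x.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs mu_x {mu_x.shape}")
    if b is None:
        b = x.shape[0]
    diff = mu_x - x
    n_lead = diff.ndim - 3
    sq = (diff * diff).sum(axis=(n_lead, n_lead + 1, n_lead + 2))
    weights = 1.0 / np.broadcast_to(
        np.asarray(size, dtype=np.float64) ** 3, sq.shape)
    return (sq * Tensor(weights)).sum() * (1.0 / b)


def kl_loss(mu, sigma, b: int | None = None, direction: str = "standard") -> Tensor:
    """Gaussian KL to the standard normal, normalized by b and d.

    ``standard`` is the usual VAE direction KL(N(mu, sigma^2) || N(0,1))
    = 1/2 (mu^2 + sigma^2 - 1 - ln sigma^2) per dimension; ``reversed``
    computes KL(N(0,1) || N(mu, sigma^2)) instead.
    """
    mu, sigma = as_tensor(mu), as_tensor(sigma)
    if np.any(sigma.data <= 0):
        raise ValueError("sigma must be strictly positive")
    if b is None:
        if mu.ndim < 2:
            raise ValueError("anchor count b required for flat inputs")
        b = mu.shape[0]
    d = mu.shape[-1]
    if direction == "standard":
        per_dim = (mu * mu + sigma * sigma - 1.0 - sigma.log() * 2.0) * 0.5
    elif direction == "reversed":
        per_dim = sigma.log() + (1.0 + mu * mu) / (sigma * sigma * 2.0) - 0.5
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return per_dim.sum() * (1.0 / (b * d))


def similarity_tensor(mu_semantic) -> Tensor:
    """Pairwise cosine similarities of the semantic embeddings.

    Input: (b, R, d_MS) semantic latent means. Output S with index
    convention S[j, i, k, l] = cos(embedding of sample i, replicate j;
    embedding of sample l, replicate k), shape (R, b, R, b). A zero
    embedding yields similarity 0 against everything.
    """
    e = as_tensor(mu_semantic)
    if e.ndim != 3:
        raise ValueError(f"expected (b, R, d_MS) embeddings, got {e.shape}")
    b, r, d = e.shape
    norm = ((e * e).sum(axis=2, keepdims=True) + _EPS).sqrt()
    unit = (e / norm).reshape(b * r, d)
    gram = unit @ unit.transpose(1, 0)           # (b*R, b*R), [(i,j),(l,k)]
    return gram.reshape(b, r, b, r).transpose(1, 0, 3, 2)


def multi_similarity_loss(S, config: LossConfig) -> Tensor:
    """Multi-similarity loss over a precomputed similarity tensor.

    For each anchor/replicate (j, i): a positive term
    (1/alpha) log[1 + sum_{k != j} exp(-alpha (S[j,i,k,i] - lambda))]
    over the sample's other replicates, and a negative term
    (1/beta) log[1 + sum_k sum_{l != i} exp(beta (S[j,i,k,l] - lambda))]
    over all replicates of all other samples; the total is averaged over
    the b (1 + n_pos) anchors. Requires b >= 2 (otherwise no negatives).
    """
    S = as_tensor(S)
    if S.ndim != 4 or S.shape[0] != S.shape[2] or S.shape[1] != S.shape[3]:
        raise ValueError(f"expected (R, b, R, b) similarity tensor, got {S.shape}")
    r, b = S.shape[0], S.shape[1]
    if b < 2:
        raise ValueError("multi-similarity loss requires b >= 2 samples")
    alpha, beta, lam = config.alpha, config.beta, config.margin

    same_sample = np.equal.outer(np.arange(b), np.arange(b))     # (i, l)
    other_replicate = ~np.eye(r, dtype=bool)                     # (j, k)
    pos_mask = (other_replicate[:, None, :, None]
                & same_sample[None, :, None, :]).astype(np.float64)
    neg_mask = np.broadcast_to(~same_sample[None, :, None, :],
                               (r, b, r, b)).astype(np.float64)

    pos_sum = (((S - lam) * (-alpha)).exp() * Tensor(pos_mask)).sum(axis=(2, 3))
    neg_sum = (((S - lam) * beta).exp() * Tensor(neg_mask)).sum(axis=(2, 3))
    terms = (pos_sum + 1.0).log() * (1.0 / alpha) \
        + (neg_sum + 1.0).log() * (1.0 / beta)
    return terms.sum() * (1.0 / (b * r))


def batch_loss(recon, kl, ms, config: LossConfig) -> Tensor:
    """Weighted sum: recon + theta_KL * KL + theta_MS * MS."""
    recon, kl, ms = as_tensor(recon), as_tensor(kl), as_tensor(ms)
    for name, term in (("reconstruction", recon), ("kl", kl), ("ms", ms)):
        if not np.all(np.isfinite(term.data)):
            raise FloatingPointError(f"non-finite {name} loss term")
    return recon + as_tensor(config.theta_kl) * kl + as_tensor(config.theta_ms) * ms
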