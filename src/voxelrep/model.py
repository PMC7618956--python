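"""The patch VAE: encoder, reparameterization, decoder, checkpointing.

Maps 16^3 intensity patches to a d-dimensional Gaussian latent
(mu_z, sigma_z) and back to a sigmoid-bounded reconstruction mu_x. The
first ``semantic_dim`` latent dimensions are, by convention, the
semantic subspace — the slice the metric loss acts on and the slice
kept at inference. That convention lives here
(:meth:`VAE.semantic_slice`) and nowhere else.

The default network is fully connected (4096 -> 256 -> 64 -> heads, a
mirrored decoder); at 16^3 inputs this is expressive enough for local
texture while keeping the NumPy forward/backward pass fast on one CPU
core.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["VAEConfig", "VAE", "Adam", "save_checkpoint", "load_checkpoint"]

PATCH_POINTS = 16
_PATCH_SIZE = PATCH_POINTS**3


@dataclass
class VAEConfig:
    """Latent dimensionality and encoder width.

    ``latent_dim`` is d; ``semantic_dim`` is d_MS, the leading slice that
    receives the metric-learning signal (default 8 of 64).
    """

    latent_dim: int = 64
    semantic_dim: int = 8
    hidden_sizes: tuple[int, ...] = (256, 64)
    patch_points: int = PATCH_POINTS
    logvar_min: float = -18.0   # sigma ~ 1e-4
    logvar_max: float = 4.6     # sigma ~ 10

    def __post_init__(self):
        self.hidden_sizes = tuple(self.hidden_sizes)
        if not (0 < self.semantic_dim <= self.latent_dim):
            raise ValueError("require 0 < semantic_dim <= latent_dim")
        if self.patch_points != PATCH_POINTS:
            raise ValueError(f"patch_points must be {PATCH_POINTS}")


def _init_linear(rng, n_in: int, n_out: int) -> tuple[Tensor, Tensor]:
    w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
    b = np.zeros(n_out, dtype=np.float32)
    return Tensor(w, requires_grad=True), Tensor(b, requires_grad=True)


class VAE:
    """Fully connected 3D-patch variational autoencoder."""

    def __init__(self, config: VAEConfig | None = None, seed: int = 0):
        self.config = config or VAEConfig()
        rng = np.random.default_rng(seed)
        d, hidden = self.config.latent_dim, self.config.hidden_sizes

        self.enc_layers = []
        n_in = _PATCH_SIZE
        for h in hidden:
            self.enc_layers.append(_init_linear(rng, n_in, h))
            n_in = h
        self.w_mu, self.b_mu = _init_linear(rng, n_in, d)
        self.w_lv, self.b_lv = _init_linear(rng, n_in, d)

        self.dec_layers = []
        n_in = d
        for h in reversed(hidden):
            self.dec_layers.append(_init_linear(rng, n_in, h))
            n_in = h
        self.dec_layers.append(_init_linear(rng, n_in, _PATCH_SIZE))

    # -- parameters -----------------------------------------------------
    @property
    def parameters(self) -> list[Tensor]:
        params = []
        for w, b in self.enc_layers:
            params += [w, b]
        params += [self.w_mu, self.b_mu, self.w_lv, self.b_lv]
        for w, b in self.dec_layers:
            params += [w, b]
        return params

    def semantic_slice(self, mu: np.ndarray) -> np.ndarray:
        """The semantic subspace: the leading d_MS latent dimensions."""
        return mu[..., : self.config.semantic_dim]

    # -- forward --------------------------------------------------------
    def _flatten(self, x) -> Tensor:
        x = as_tensor(x)
        n = self.config.patch_points
        if x.ndim >= 3 and x.shape[-3:] == (n, n, n):
            x = x.reshape(*x.shape[:-3], _PATCH_SIZE)
        if x.shape[-1] != _PATCH_SIZE:
            raise ValueError(
                f"expected {n}^3 patches, got trailing shape {x.shape[-3:]}")
        if x.ndim == 1:
            x = x.reshape(1, _PATCH_SIZE)
        elif x.ndim > 2:
            x = x.reshape(-1, _PATCH_SIZE)
        return x

    def encode(self, x) -> tuple[Tensor, Tensor]:
        """Patches -> (mu_z, sigma_z); deterministic given the weights.

        ``sigma_z`` is exp(logvar / 2) with logvar clamped for stability,
        hence strictly positive.
        """
        # intensities live in [0, 1]; centring keeps the first layer
        # well-conditioned
        h = self._flatten(x) - 0.5
        for w, b in self.enc_layers:
            h = (h @ w + b).relu()
        mu = h @ self.w_mu + self.b_mu
        logvar = (h @ self.w_lv + self.b_lv).clip(
            self.config.logvar_min, self.config.logvar_max)
        sigma = (logvar * 0.5).exp()
        return mu, sigma

    @staticmethod
    def reparameterize(mu: Tensor, sigma: Tensor,
                       rng: np.random.Generator) -> Tensor:
        """z = mu + sigma * eps with eps ~ N(0, I)."""
        mu, sigma = as_tensor(mu), as_tensor(sigma)
        eps = rng.standard_normal(mu.shape).astype(np.float32)
        return mu + sigma * Tensor(eps)

    def decode(self, z) -> Tensor:
        """Latent codes -> sigmoid-bounded 16^3 reconstructions mu_x."""
        z = as_tensor(z)
        if z.ndim == 1:
            z = z.reshape(1, -1)
        if z.shape[-1] != self.config.latent_dim:
            raise ValueError(
                f"latent dimension {z.shape[-1]} != {self.config.latent_dim}")
        h = z
        for w, b in self.dec_layers[:-1]:
            h = (h @ w + b).relu()
        w, b = self.dec_layers[-1]
        out = (h @ w + b).sigmoid()
        n = self.config.patch_points
        return out.reshape(*z.shape[:-1], n, n, n)

    # -- fast inference path (no graph) ---------------------------------
    def encode_mu_np(self, x: np.ndarray) -> np.ndarray:
        """Latent mean only, plain NumPy — the dense-inference hot path."""
        x = np.asarray(x, dtype=np.float32)
        h = x.reshape(-1, _PATCH_SIZE) - 0.5
        for w, b in self.enc_layers:
            h = np.maximum(h @ w.data + b.data, 0.0)
        return h @ self.w_mu.data + self.b_mu.data


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def save_checkpoint(model: VAE, path: str, extra: dict | None = None) -> None:
    """Weights + embedded VAEConfig (and optional metadata) in one .npz."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters)}
    meta = {"config": asdict(model.config), "extra": extra or {}}
    arrays["meta"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> VAE:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode("utf-8"))
        cfg = meta["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        model = VAE(VAEConfig(**cfg))
        for i, p in enumerate(model.parameters):
            loaded = data[f"param_{i}"]
            if loaded.shape != p.data.shape:
                raise ValueError(f"checkpoint/config mismatch at parameter {i}")
            p.data = loaded
    return model
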