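"""Self-supervised training loop and the sklearn-style estimator.

One optimization step: draw b anchor grids (round-robin across training
volumes), n_pos positive grids per anchor, extract and augment the
(1 + n_pos) * b patches, run the VAE forward, evaluate the combined
loss, backpropagate and take an Adam step. Training stops after a fixed
anchor budget (``anchors_per_stack`` per training volume) — no early
stopping.

:class:`VoxelRepresentation` packages the whole method as a scikit-learn
transformer: ``fit`` trains the VAE on a list of volumes, ``transform``
densely encodes a volume into its per-voxel semantic latent map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import losses as L
from .model import VAE, Adam, VAEConfig
from .sampling import (AugmentationConfig, augment_flips, augment_photometric,
                       extract_patches, sample_anchor_grids,
                       sample_positive_grids)
from .volume_io import Volume

__all__ = ["TrainConfig", "train", "VoxelRepresentation"]


@dataclass
class TrainConfig:
    """Budget and batch composition of a training run.

    ``anchors_per_stack`` anchors are consumed per training volume (the
    full-scale runs in the field use millions; the desk default of
    20,000 trains in minutes on one CPU core). Each batch holds
    ``batch_anchors`` anchors with ``n_pos`` positives each.
    """

    anchors_per_stack: int = 20_000
    batch_anchors: int = 128
    n_pos: int = 4
    size_range: tuple[float, float] = (4.0, 12.0)
    vae: VAEConfig = field(default_factory=VAEConfig)
    loss: LossConfig = None  # type: ignore[assignment]
    aug: AugmentationConfig = field(default_factory=AugmentationConfig)
    learning_rate: float = 3e-3
    seed: int = 0

    def __post_init__(self):
        if self.loss is None:
            self.loss = L.LossConfig()
        if self.anchors_per_stack < self.batch_anchors:
            raise ValueError("anchors_per_stack must be >= batch_anchors")


LossConfig = L.LossConfig  # re-export for config assembly


def _as_volume(v) -> Volume:
    return v if isinstance(v, Volume) else Volume(np.asarray(v, dtype=np.float64))


def train(volumes: list[Volume], config: TrainConfig,
          callback=None) -> tuple[VAE, list[dict]]:
    """Train a VAE on one or more volumes; returns (model, log).

    The log holds one row per step with every loss component. Anchors
    are allocated round-robin across volumes within each batch.
    Deterministic for a fixed ``config.seed``.
    """
    volumes = [_as_volume(v) for v in volumes]
    if not volumes:
        raise ValueError("at least one training volume required")
    # float32 views so patch extraction avoids a per-step conversion
    volumes = [Volume(np.ascontiguousarray(v.data, dtype=np.float32),
                      spacing=v.spacing) for v in volumes]
    rng = np.random.default_rng(config.seed)
    model = VAE(config.vae, seed=config.seed)
    opt = Adam(model.parameters, lr=config.learning_rate)
    b, n_pos = config.batch_anchors, config.n_pos
    n_steps = (config.anchors_per_stack * len(volumes)) // b
    log: list[dict] = []

    for step in range(n_steps):
        x, sizes = _sample_batch(volumes, config, rng, step)
        total, parts = _loss_forward(model, x, sizes, config, rng)
        for name, value in parts.items():
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"{name} loss became non-finite at step {step}")
        opt.zero_grad()
        total.backward()
        opt.step()
        row = {"step": step, **parts}
        log.append(row)
        if callback is not None:
            callback(row)
    return model, log


def _sample_batch(volumes, config: TrainConfig, rng, step: int):
    """One batch of augmented patches: (b, 1+n_pos, 16, 16, 16) float32
    plus the matching physical sizes (b, 1+n_pos)."""
    b, n_pos = config.batch_anchors, config.n_pos
    n_vol = len(volumes)
    grids_per_volume: list[list] = [[] for _ in volumes]
    order = []
    for i in range(b):
        v = (step * b + i) % n_vol
        anchor = sample_anchor_grids(volumes[v], 1, config.size_range, rng)[0]
        group = [anchor] + sample_positive_grids(anchor, n_pos, config.aug, rng)
        order.append((v, len(grids_per_volume[v])))
        grids_per_volume[v].extend(group)

    patches_per_volume = [
        extract_patches(vol, grids) if grids else None
        for vol, grids in zip(volumes, grids_per_volume)
    ]
    r = 1 + n_pos
    x = np.empty((b, r, 16, 16, 16), dtype=np.float32)
    sizes = np.empty((b, r), dtype=np.float64)
    for i, (v, offset) in enumerate(order):
        x[i] = patches_per_volume[v][offset: offset + r]
        sizes[i] = [g.size for g in grids_per_volume[v][offset: offset + r]]

    flat = augment_flips(x.reshape(b * r, 16, 16, 16), config.aug.flip_prob, rng)
    flat = augment_photometric(flat, config.aug, rng)
    return flat.reshape(b, r, 16, 16, 16), sizes


def _loss_forward(model: VAE, x: np.ndarray, sizes: np.ndarray,
                  config: TrainConfig, rng):
    """Forward pass and combined loss on one batch."""
    b, r = x.shape[:2]
    mu, sigma = model.encode(x)                      # (b*r, d)
    z = model.reparameterize(mu, sigma, rng)
    mu_x = model.decode(z)                           # (b*r, 16,16,16)
    recon = L.reconstruction_loss(
        x.reshape(b * r, 16, 16, 16), mu_x, sizes.reshape(-1), b=b)
    kl = L.kl_loss(mu, sigma, b=b, direction=config.loss.kl_direction)
    d_ms = model.config.semantic_dim
    sem = mu.reshape(b, r, model.config.latent_dim)[:, :, :d_ms]
    ms = L.multi_similarity_loss(L.similarity_tensor(sem), config.loss)
    total = L.batch_loss(recon, kl, ms, config.loss)
    parts = {"recon": recon.item(), "kl": kl.item(), "ms": ms.item(),
             "total": total.item()}
    return total, parts


class VoxelRepresentation(BaseEstimator, TransformerMixin):
    """Self-supervised voxel-level representation, sklearn style.

    ``fit(X)`` trains the patch VAE on a list of 3D volumes (arrays or
    :class:`Volume`); ``transform(volume)`` densely encodes every voxel
    into the semantic latent subspace, returning a
    :class:`~voxelrep.inference.LatentVolume`.

    Parameters mirror the training configuration; see
    :class:`TrainConfig`, :class:`~voxelrep.model.VAEConfig`,
    :class:`~voxelrep.losses.LossConfig` and
    :class:`~voxelrep.sampling.AugmentationConfig` for semantics.
    """

    def __init__(self, latent_dim=64, semantic_dim=8, hidden_sizes=(256, 64),
                 anchors_per_stack=20_000, batch_anchors=128, n_pos=4,
                 size_min=4.0, size_max=12.0, learning_rate=3e-3,
                 theta_kl=0.1, theta_ms=1.0, alpha=2.0, beta=50.0, margin=1.0,
                 positive_radius=2.0, noise_sd=0.03, random_state=0):
        self.latent_dim = latent_dim
        self.semantic_dim = semantic_dim
        self.hidden_sizes = hidden_sizes
        self.anchors_per_stack = anchors_per_stack
        self.batch_anchors = batch_anchors
        self.n_pos = n_pos
        self.size_min = size_min
        self.size_max = size_max
        self.learning_rate = learning_rate
        self.theta_kl = theta_kl
        self.theta_ms = theta_ms
        self.alpha = alpha
        self.beta = beta
        self.margin = margin
        self.positive_radius = positive_radius
        self.noise_sd = noise_sd
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            anchors_per_stack=self.anchors_per_stack,
            batch_anchors=self.batch_anchors,
            n_pos=self.n_pos,
            size_range=(self.size_min, self.size_max),
            vae=VAEConfig(latent_dim=self.latent_dim,
                          semantic_dim=self.semantic_dim,
                          hidden_sizes=tuple(self.hidden_sizes)),
            loss=L.LossConfig(theta_kl=self.theta_kl, theta_ms=self.theta_ms,
                              alpha=self.alpha, beta=self.beta,
                              margin=self.margin),
            aug=AugmentationConfig(positive_radius=self.positive_radius,
                                   size_bounds=(self.size_min, self.size_max),
                                   noise_sd=self.noise_sd),
            learning_rate=self.learning_rate,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        if isinstance(X, (Volume, np.ndarray)):
            X = [X]
        config = self._train_config()
        self.model_, self.log_ = train(list(X), config)
        self.n_steps_ = len(self.log_)
        return self

    def transform(self, X, chunk=(4, 32, 32)):
        from .inference import encode_volume
        if not hasattr(self, "model_"):
            raise RuntimeError("VoxelRepresentation is not fitted")
        return encode_volume(self.model_, _as_volume(X), chunk=chunk)
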