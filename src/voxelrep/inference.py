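"""Dense voxel-level inference and the subspace-invariance measurement.

At inference every voxel of a volume is represented by the latent mean
of the fixed-size (a = 8), fixed-orientation patch centred on it; only
the semantic dimensions mu_z[0:d_MS] are kept (no sampling of z). The
result is a :class:`LatentVolume`, a channels-first 4D float32 field.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy.spatial.distance import pdist

from .model import VAE
from .sampling import GRID_POINTS, INFERENCE_SIZE, dense_inference_patches
from .volume_io import Volume

__all__ = [
    "LatentVolume",
    "encode_volume",
    "subspace_invariance_score",
    "save_latent",
    "load_latent",
]


@dataclass
class LatentVolume:
    """Per-voxel semantic latent means, channels first.

    ``data`` has shape (d_MS, depth, height, width); ``size`` and
    ``grid_points`` record the inference patch geometry, ``checkpoint``
    the provenance of the encoder.
    """

    data: np.ndarray
    size: float = INFERENCE_SIZE
    grid_points: int = GRID_POINTS
    checkpoint: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError("LatentVolume data must be (channels, d, h, w)")

    @property
    def n_channels(self):
        return self.data.shape[0]

    @property
    def spatial_shape(self):
        return self.data.shape[1:]

    def vectors(self) -> np.ndarray:
        """Row-major (n_voxels, d_MS) view for clustering."""
        return self.data.reshape(self.n_channels, -1).T


def encode_volume(model: VAE, volume: Volume,
                  chunk: tuple[int, int, int] = (4, 32, 32),
                  checkpoint: str = "") -> LatentVolume:
    """Semantic latent mean of the centred a=8 patch, for every voxel.

    Deterministic (the mean is used, no sampling) and independent of
    the chunk shape; chunking only bounds memory.
    """
    d_ms = model.config.semantic_dim
    out = np.empty((d_ms,) + volume.shape, dtype=np.float32)
    for centers, patches in dense_inference_patches(volume, chunk=chunk):
        mu = model.encode_mu_np(patches)[:, :d_ms]
        out[:, centers[:, 0], centers[:, 1], centers[:, 2]] = mu.T
    return LatentVolume(out, checkpoint=checkpoint)


def subspace_invariance_score(
    model: VAE,
    pairs: list[tuple[np.ndarray, np.ndarray, int]],
    dims_a: tuple[int, int] = (0, 8),
    dims_b: tuple[int, int] = (8, 16),
) -> tuple[float, float]:
    """Transformation invariance of two latent slices; lower = more invariant.

    For each slice, the mean Euclidean distance between the latent means
    of original and transformed patches is divided by the mean pairwise
    distance among the originals in the same slice, so the two scores
    are comparable across subspaces of different scale. A trained model
    should give score(semantic) < score(non-semantic).
    """
    if len(pairs) < 1:
        raise ValueError("at least one pair required")
    if len(pairs) < 2:
        raise ValueError("at least two originals needed to normalize the score")
    originals = np.stack([p[0] for p in pairs])
    transformed = np.stack([p[1] for p in pairs])
    mu_o = model.encode_mu_np(originals)
    mu_t = model.encode_mu_np(transformed)
    scores = []
    for lo, hi in (dims_a, dims_b):
        if hi > model.config.latent_dim:
            raise ValueError(f"slice ({lo}, {hi}) exceeds latent dimension")
        o, t = mu_o[:, lo:hi], mu_t[:, lo:hi]
        displacement = np.linalg.norm(o - t, axis=1).mean()
        spread = pdist(o).mean()
        scores.append(float(displacement / spread) if spread > 0 else 0.0)
    return scores[0], scores[1]


def save_latent(latent: LatentVolume, path: str, dataset_key: str = "latent") -> None:
    with h5py.File(path, "a") as f:
        if dataset_key in f:
            del f[dataset_key]
        ds = f.create_dataset(dataset_key, data=latent.data)
        ds.attrs["size"] = latent.size
        ds.attrs["grid_points"] = latent.grid_points
        ds.attrs["checkpoint"] = latent.checkpoint


def load_latent(path: str, dataset_key: str = "latent") -> LatentVolume:
    with h5py.File(path, "r") as f:
        ds = f[dataset_key]
        return LatentVolume(ds[()], size=float(ds.attrs.get("size", INFERENCE_SIZE)),
                            grid_points=int(ds.attrs.get("grid_points", GRID_POINTS)),
                            checkpoint=str(ds.attrs.get("checkpoint", "")))
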