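"""Mini-batch k-means clustering of the semantic latent volume.

Full volumes yield one d_MS-vector per voxel — hundreds of millions at
realistic scale — so centroids are learned by streaming mini-batch
k-means (k-means++ initialization on a subsample, then mini-batch
updates), which scales where full-batch k-means does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import MiniBatchKMeans

from .inference import LatentVolume
from .volume_io import LabelVolume

__all__ = ["ClusterConfig", "cluster_latent", "LatentKMeans"]

logger = logging.getLogger(__name__)


@dataclass
class ClusterConfig:
    """k and the mini-batch schedule (k typically 4-10)."""

    k: int = 4
    batch_size: int = 10_000
    n_init: int = 3
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")


def cluster_latent(latent: LatentVolume, config: ClusterConfig) -> LabelVolume:
    """Cluster per-voxel semantic vectors into ``config.k`` classes.

    Returns an integer label volume (labels 0..k-1, identities
    arbitrary — semantic correspondence is established only by the
    evaluation matching). Deterministic for a fixed seed. Raises if the
    data holds fewer distinct vectors than k.
    """
    x = latent.vectors()
    if not np.all(np.isfinite(x)):
        raise ValueError("latent volume contains non-finite values")
    n_distinct = len(np.unique(x, axis=0))
    if n_distinct < config.k:
        raise ValueError(
            f"only {n_distinct} distinct latent vectors for k={config.k}")
    km = MiniBatchKMeans(
        n_clusters=config.k,
        batch_size=config.batch_size,
        n_init=config.n_init,
        max_iter=config.max_iter,
        random_state=config.seed,
    )
    flat = km.fit_predict(x)
    used = np.unique(flat)
    if len(used) < config.k:
        logger.warning("only %d of %d cluster labels used", len(used), config.k)
    return LabelVolume(flat.astype(np.int64).reshape(latent.spatial_shape))


class LatentKMeans(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper: fit_predict(LatentVolume) -> LabelVolume."""

    def __init__(self, k=4, batch_size=10_000, n_init=3, max_iter=200,
                 random_state=0):
        self.k = k
        self.batch_size = batch_size
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit_predict(self, X: LatentVolume, y=None) -> LabelVolume:
        config = ClusterConfig(k=self.k, batch_size=self.batch_size,
                               n_init=self.n_init, max_iter=self.max_iter,
                               seed=self.random_state)
        self.labels_ = cluster_latent(X, config)
        return self.labels_

    def fit(self, X, y=None):
        self.fit_predict(X)
        return self
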