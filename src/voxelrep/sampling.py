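"""Anchor/positive sampling grids, patch extraction and augmentation.

A :class:`SamplingGrid` is a 16x16x16 lattice of continuous coordinates:
the 16 points per axis span a closed cube of physical edge length ``a``
(spacing ``a/15``) centred on a continuous voxel coordinate, optionally
rotated and sheared. Training anchors draw ``a`` uniformly from [4, 12];
inference fixes ``a = 8``, i.e. each patch resamples the 9^3 voxel
neighbourhood of its centre voxel onto the 16^3 lattice.

Patches are extracted by trilinear interpolation
(:func:`scipy.ndimage.map_coordinates`, order 1) with reflection padding
at the borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .volume_io import Volume

__all__ = [
    "SamplingGrid",
    "AugmentationConfig",
    "sample_anchor_grids",
    "sample_positive_grids",
    "extract_patch",
    "extract_patches",
    "augment_photometric",
    "augment_flips",
    "dense_inference_patches",
    "random_rotation",
]

GRID_POINTS = 16
INFERENCE_SIZE = 8.0
_PAD_MODE = "mirror"  # scipy name for reflection about the edge sample


@dataclass
class SamplingGrid:
    """One patch-defining lattice: position, size, orientation, deformation."""

    center: np.ndarray                      # (z, y, x), continuous voxels
    size: float                             # physical edge length a
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    deformation: np.ndarray = field(default_factory=lambda: np.eye(3))
    grid_points: int = GRID_POINTS

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64)
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.deformation = np.asarray(self.deformation, dtype=np.float64)
        if self.center.shape != (3,):
            raise ValueError("center must be a (z, y, x) triple")

    def coordinates(self) -> np.ndarray:
        """The (3, n, n, n) array of sample coordinates in volume space."""
        n = self.grid_points
        half = self.size / 2.0
        axis = np.linspace(-half, half, n)
        u = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"))  # (3,n,n,n)
        m = self.rotation @ self.deformation
        coords = np.einsum("ij,jabc->iabc", m, u)
        return coords + self.center[:, None, None, None]


@dataclass
class AugmentationConfig:
    """Geometric and photometric augmentation ranges for positives.

    Positive grids rotate freely (uniform over SO(3) by default), shear
    by ``I + U(-deform, deform)`` and jitter their physical size
    multiplicatively within ``size_bounds``. Photometric augmentation is
    a brightness shift, a contrast scaling about the patch mean and
    additive Gaussian noise, with the result clipped back to [0, 1].
    """

    flip_prob: float = 0.5
    rotation: str = "full"                  # 'full' | 'axis90' | 'none'
    deform: float = 0.1
    scale_jitter: tuple[float, float] = (0.8, 1.25)
    size_bounds: tuple[float, float] = (4.0, 12.0)
    positive_radius: float = 2.0            # r_pos, voxels
    brightness: tuple[float, float] = (-0.1, 0.1)
    contrast: tuple[float, float] = (0.8, 1.25)
    noise_sd: float = 0.03

    def __post_init__(self):
        if self.positive_radius <= 0:
            raise ValueError("positive_radius must be > 0")
        if self.rotation not in ("full", "axis90", "none"):
            raise ValueError(f"unknown rotation mode {self.rotation!r}")


def random_rotation(rng: np.random.Generator, mode: str = "full") -> np.ndarray:
    """A random 3D rotation matrix: uniform over SO(3), the 24-element
    axis-aligned 90-degree subgroup, or the identity."""
    if mode == "none":
        return np.eye(3)
    if mode == "axis90":
        while True:
            perm = rng.permutation(3)
            signs = rng.choice([-1.0, 1.0], size=3)
            m = np.zeros((3, 3))
            m[np.arange(3), perm] = signs
            if np.linalg.det(m) > 0:
                return m
    # uniform via random unit quaternion
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _uniform_ball(rng: np.random.Generator, radius: float, n: int = 1) -> np.ndarray:
    """n points uniform in the solid ball of the given radius."""
    direction = rng.standard_normal((n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.uniform(0.0, 1.0, size=(n, 1)) ** (1.0 / 3.0)
    return direction * r


def sample_anchor_grids(
    volume: Volume,
    n: int,
    size_range: tuple[float, float] = (4.0, 12.0),
    rng: np.random.Generator | None = None,
) -> list[SamplingGrid]:
    """Draw ``n`` anchor grids: sizes uniform over ``size_range``, centres
    uniform over voxels at which the (unrotated) grid fits inside the
    volume; anchors carry identity rotation and deformation."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng() if rng is None else rng
    lo, hi = size_range
    shape = np.asarray(volume.shape, dtype=np.float64)
    if np.any(shape - 1 < hi):
        raise ValueError(
            f"volume shape {volume.shape} too small for grids of size {hi}")
    sizes = rng.uniform(lo, hi, size=n)
    grids = []
    for a in sizes:
        half = a / 2.0
        center = rng.uniform(half, shape - 1 - half)
        grids.append(SamplingGrid(center=center, size=float(a)))
    return grids


def sample_positive_grids(
    anchor: SamplingGrid,
    n_pos: int,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> list[SamplingGrid]:
    """Positives share the anchor's neighbourhood: centres offset
    uniformly within a ball of radius ``r_pos``, with independent random
    rotation, shear and relative size jitter."""
    offsets = _uniform_ball(rng, config.positive_radius, n_pos)
    lo, hi = config.size_bounds
    grids = []
    for i in range(n_pos):
        size = float(np.clip(anchor.size * rng.uniform(*config.scale_jitter), lo, hi))
        rot = random_rotation(rng, config.rotation)
        deform = np.eye(3) + rng.uniform(-config.deform, config.deform, (3, 3))
        grids.append(SamplingGrid(center=anchor.center + offsets[i], size=size,
                                  rotation=rot, deformation=deform))
    return grids


_UNIT_LATTICE_CACHE: dict[int, np.ndarray] = {}


def _unit_lattice(gp: int) -> np.ndarray:
    """(3, gp^3) lattice spanning [-1/2, 1/2] per axis, cached."""
    if gp not in _UNIT_LATTICE_CACHE:
        axis = np.linspace(-0.5, 0.5, gp)
        u = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"))
        _UNIT_LATTICE_CACHE[gp] = u.reshape(3, -1)
    return _UNIT_LATTICE_CACHE[gp]


def extract_patches(volume: Volume, grids: list[SamplingGrid]) -> np.ndarray:
    """Trilinearly sample all grids in one call; (n, 16, 16, 16).

    Interpolation runs in the volume's own float dtype (the training
    loop pre-converts volumes to float32 for speed; float64 input gives
    float64-accurate patches).
    """
    n = len(grids)
    gp = grids[0].grid_points
    u = _unit_lattice(gp)
    mats = np.stack([g.size * (g.rotation @ g.deformation) for g in grids])
    centers = np.stack([g.center for g in grids])
    coords = np.einsum("nij,jp->inp", mats, u) + centers.T[:, :, None]
    data = volume.data
    if data.dtype not in (np.float32, np.float64) or not data.flags.c_contiguous:
        data = np.ascontiguousarray(data, dtype=np.float64)
    out = map_coordinates(data, coords.reshape(3, -1).astype(data.dtype),
                          order=1, mode=_PAD_MODE)
    return out.reshape(n, gp, gp, gp)


def extract_patch(volume: Volume, grid: SamplingGrid) -> np.ndarray:
    """Trilinear interpolation of the volume at the grid's 16^3 lattice."""
    return extract_patches(volume, [grid])[0]


def augment_photometric(
    patch: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Brightness shift, contrast scaling about the patch mean, additive
    Gaussian noise; clipped to [0, 1]. Works on one patch or a stack
    (leading batch axis), with independent draws per patch."""
    patch = np.asarray(patch, dtype=np.float32)
    single = patch.ndim == 3
    x = patch[None] if single else patch
    n = x.shape[0]
    bright = rng.uniform(*config.brightness, size=(n, 1, 1, 1)).astype(np.float32)
    contr = rng.uniform(*config.contrast, size=(n, 1, 1, 1)).astype(np.float32)
    mean = x.mean(axis=(1, 2, 3), keepdims=True)
    out = (x - mean) * contr + mean + bright
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, x.shape).astype(np.float32)
    out = np.clip(out, 0.0, 1.0)
    return out[0] if single else out


def augment_flips(
    patches: np.ndarray,
    flip_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent random axis flips per patch (stack with batch axis)."""
    out = np.array(patches)
    for axis in range(3):
        mask = rng.uniform(size=out.shape[0]) < flip_prob
        if mask.any():
            out[mask] = np.flip(out[mask], axis=axis + 1)
    return out


def _mirror_indices(lo: int, hi: int, n: int) -> np.ndarray:
    """Indices lo..hi-1 folded into 0..n-1 by reflection about the edge
    samples (the same convention as scipy's 'mirror' mode)."""
    t = np.arange(lo, hi)
    if n == 1:
        return np.zeros_like(t)
    period = 2 * n - 2
    t = np.abs(t) % period
    return np.where(t >= n, period - t, t)


def dense_inference_patches(
    volume: Volume,
    chunk: tuple[int, int, int] = (4, 32, 32),
    size: float = INFERENCE_SIZE,
    grid_points: int = GRID_POINTS,
):
    """Yield, chunk by chunk, the fixed-size axis-aligned patch centred
    on every voxel.

    Yields ``(centers, patches)`` where ``centers`` is an (n, 3) integer
    array of voxel coordinates (row-major within the chunk) and
    ``patches`` is (n, 16, 16, 16) float32. Chunks iterate row-major
    over the volume; every voxel appears exactly once, and the patch for
    a given voxel does not depend on the chunking.

    Because the dense lattice is axis-aligned with voxel-integer
    centres, every lattice point has a constant fractional offset, so
    patches are assembled by separable per-axis linear interpolation of
    shifted views — exactly equivalent to trilinear resampling with
    reflection padding, but far faster than per-point interpolation.
    """
    if volume.data.size == 0:
        raise ValueError("volume is empty")
    shape = volume.shape
    chunk = tuple(min(c, s) for c, s in zip(chunk, shape))
    gp = grid_points
    delta = np.linspace(-size / 2.0, size / 2.0, gp)
    base = np.floor(delta).astype(int)          # integer part of each offset
    frac = (delta - base).astype(np.float32)
    m = int(base[-1]) + 1                       # padding margin
    pad_idx = [_mirror_indices(-m, s + m + 1, s) for s in shape]
    padded = np.ascontiguousarray(
        volume.data, dtype=np.float32)[np.ix_(*pad_idx)]

    for z0 in range(0, shape[0], chunk[0]):
        for y0 in range(0, shape[1], chunk[1]):
            for x0 in range(0, shape[2], chunk[2]):
                zs = np.arange(z0, min(z0 + chunk[0], shape[0]))
                ys = np.arange(y0, min(y0 + chunk[1], shape[1]))
                xs = np.arange(x0, min(x0 + chunk[2], shape[2]))
                nz, ny, nx = len(zs), len(ys), len(xs)
                # extended padded-space index windows for the two outer axes
                ze0, ze1 = zs[0] + m + base[0], zs[-1] + m + base[-1] + 1
                ye0, ye1 = ys[0] + m + base[0], ys[-1] + m + base[-1] + 1
                ez, ey = ze1 - ze0 + 1, ye1 - ye0 + 1
                vx = np.empty((ez, ey, nx, gp), dtype=np.float32)
                for k in range(gp):
                    xp = xs[0] + m + base[k]
                    b0 = padded[ze0:ze1 + 1, ye0:ye1 + 1, xp:xp + nx]
                    b1 = padded[ze0:ze1 + 1, ye0:ye1 + 1, xp + 1:xp + 1 + nx]
                    vx[..., k] = (1.0 - frac[k]) * b0 + frac[k] * b1
                vxy = np.empty((ez, ny, nx, gp, gp), dtype=np.float32)
                for k in range(gp):
                    yl = ys[0] + m + base[k] - ye0
                    b0 = vx[:, yl:yl + ny]
                    b1 = vx[:, yl + 1:yl + 1 + ny]
                    vxy[:, :, :, k, :] = (1.0 - frac[k]) * b0 + frac[k] * b1
                patches = np.empty((nz, ny, nx, gp, gp, gp), dtype=np.float32)
                for k in range(gp):
                    zl = zs[0] + m + base[k] - ze0
                    b0 = vxy[zl:zl + nz]
                    b1 = vxy[zl + 1:zl + 1 + nz]
                    patches[:, :, :, k] = (1.0 - frac[k]) * b0 + frac[k] * b1
                centers = np.stack(np.meshgrid(zs, ys, xs, indexing="ij"),
                                   axis=-1).reshape(-1, 3)
                yield centers, patches.reshape(-1, gp, gp, gp)
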