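"""Synthetic textured phantoms for training and evaluating the pipeline.

Volume EM distinguishes organelles largely by local texture: mitochondria
show oriented cristae stripes, granules appear as dark cores on a bright
surround, nucleoplasm is speckled chromatin, cytosol is comparatively
smooth. The phantom generator emulates exactly this statistical structure:
a volume is partitioned into a few contiguous regions (ellipsoids, tubes,
background), each filled with one of four texture archetypes plus
additive Gaussian noise, alongside a ground-truth label volume.

Texture patterns are mean-centred within their region, so with
``noise_sd = 0`` the mean intensity of a region equals its texture's
``intensity_mean`` exactly — convenient for closed-form checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .sampling import SamplingGrid, extract_patch, random_rotation, _uniform_ball
from .volume_io import LabelVolume, Volume

__all__ = [
    "TextureSpec",
    "RegionSpec",
    "PhantomSpec",
    "generate_phantom",
    "default_phantom_spec",
    "generate_transformed_pairs",
]

TEXTURE_KINDS = ("stripes", "blobs", "smooth", "speckle")
GEOMETRIES = ("ellipsoid", "tube", "background")


@dataclass
class TextureSpec:
    """Parameters of one texture archetype.

    ``intensity_mean`` sets the region mean; ``intensity_contrast`` the
    peak-to-trough amplitude of the pattern; ``noise_sd`` the additive
    Gaussian noise. ``orientation`` (stripes only) fixes the grating
    normal; None draws it from the region's RNG.
    """

    kind: str
    period: float = 4.0            # stripes: grating period, voxels
    blob_radius: float = 2.0       # blobs: sphere radius, voxels
    intensity_mean: float = 0.5
    intensity_contrast: float = 0.3
    noise_sd: float = 0.02
    orientation: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.kind not in TEXTURE_KINDS:
            raise ValueError(f"unknown texture kind {self.kind!r}")
        if self.period < 2:
            raise ValueError("stripe period must be >= 2 voxels")
        if self.blob_radius < 1:
            raise ValueError("blob_radius must be >= 1 voxel")
        if not (0.0 <= self.intensity_mean <= 1.0
                and 0.0 <= self.intensity_contrast <= 1.0):
            raise ValueError("intensity_mean/contrast must lie in [0, 1]")


@dataclass
class RegionSpec:
    """One labelled region: a geometry, its texture, and a class label.

    Ellipsoids take ``center`` and ``radii``; tubes (cylinders) take
    ``start``, ``end`` and ``radius``. ``background`` covers everything
    not claimed by another region and must carry label 0.
    """

    geometry: str
    texture: TextureSpec
    label: int
    name: str = ""
    center: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] | None = None
    start: tuple[float, float, float] | None = None
    end: tuple[float, float, float] | None = None
    radius: float | None = None

    def __post_init__(self):
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    regions: list[RegionSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if any(s < 32 for s in self.shape):
            raise ValueError("each phantom dimension must be >= 32")
        labels = sorted(r.label for r in self.regions)
        if labels != list(range(len(self.regions))):
            raise ValueError("region labels must be unique and contiguous from 0")
        bg = [r for r in self.regions if r.geometry == "background"]
        if len(bg) != 1 or bg[0].label != 0:
            raise ValueError("exactly one background region with label 0 required")
        shape = np.asarray(self.shape, dtype=np.float64)
        for r in self.regions:
            if r.geometry == "ellipsoid":
                c, rad = np.asarray(r.center), np.asarray(r.radii)
                if np.any(c - rad < 0) or np.any(c + rad > shape - 1):
                    raise ValueError(f"ellipsoid {r.label} out of bounds")
            elif r.geometry == "tube":
                for p in (np.asarray(r.start), np.asarray(r.end)):
                    if np.any(p - r.radius < 0) or np.any(p + r.radius > shape - 1):
                        raise ValueError(f"tube {r.label} out of bounds")


def _region_mask(region: RegionSpec, shape: tuple[int, int, int]) -> np.ndarray:
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                                indexing="ij"), axis=-1)
    if region.geometry == "background":
        return np.ones(shape, dtype=bool)
    if region.geometry == "ellipsoid":
        c = np.asarray(region.center, dtype=np.float64)
        r = np.asarray(region.radii, dtype=np.float64)
        return (((grid - c) / r) ** 2).sum(axis=-1) <= 1.0
    # tube: distance to the segment start-end
    p0 = np.asarray(region.start, dtype=np.float64)
    p1 = np.asarray(region.end, dtype=np.float64)
    d = p1 - p0
    t = np.clip(((grid - p0) @ d) / (d @ d), 0.0, 1.0)
    closest = p0 + t[..., None] * d
    return ((grid - closest) ** 2).sum(axis=-1) <= region.radius**2


def _texture_pattern(tex: TextureSpec, shape: tuple[int, int, int],
                     mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean (over the mask) pattern of amplitude ~ intensity_contrast."""
    amp = tex.intensity_contrast / 2.0
    if tex.kind == "smooth":
        pattern = np.zeros(shape)
    elif tex.kind == "stripes":
        if tex.orientation is not None:
            normal = np.asarray(tex.orientation, dtype=np.float64)
        else:
            normal = rng.standard_normal(3)
        normal = normal / np.linalg.norm(normal)
        phase = rng.uniform(0, 2 * np.pi)
        grid = np.stack(np.meshgrid(*[np.arange(s, dtype=np.float64)
                                      for s in shape], indexing="ij"), axis=-1)
        pattern = amp * np.sin(2 * np.pi * (grid @ normal) / tex.period + phase)
    elif tex.kind == "speckle":
        raw = rng.standard_normal(shape)
        raw = gaussian_filter(raw, sigma=0.6)
        pattern = amp * raw / raw.std()
    else:  # blobs: dark spheres on a brighter surround
        pattern = np.zeros(shape)
        n_vox = int(mask.sum())
        blob_vol = 4.0 / 3.0 * np.pi * tex.blob_radius**3
        n_blobs = max(1, int(0.25 * n_vox / blob_vol))
        candidates = np.argwhere(mask)
        centers = candidates[rng.integers(0, len(candidates), size=n_blobs)]
        r_int = int(np.ceil(tex.blob_radius))
        ax = np.arange(-r_int, r_int + 1, dtype=np.float64)
        ball = (np.stack(np.meshgrid(ax, ax, ax, indexing="ij"))**2
                ).sum(axis=0) <= tex.blob_radius**2
        for c in centers:
            sl, cut = [], []
            ok = True
            for dim, cc in enumerate(c):
                lo, hi = cc - r_int, cc + r_int + 1
                clo, chi = max(lo, 0), min(hi, shape[dim])
                if clo >= chi:
                    ok = False
                    break
                sl.append(slice(clo, chi))
                cut.append(slice(clo - lo, (2 * r_int + 1) - (hi - chi)))
            if ok:
                sub = pattern[tuple(sl)]
                sub[ball[tuple(cut)]] = -2.0 * amp
    pattern = pattern - pattern[mask].mean()
    # keep mean + pattern strictly inside [0, 1] so the final clip never
    # bites (preserves the exact region-mean property at noise_sd = 0)
    lim = 0.95 * min(tex.intensity_mean, 1.0 - tex.intensity_mean)
    if lim > 0:
        pattern = np.clip(pattern, -lim, lim)
        pattern = pattern - pattern[mask].mean()
    return pattern


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelVolume]:
    """Render the phantom: an intensity volume in [0, 1] and its labels.

    Regions are painted in list order, so a later region overwrites any
    earlier one where geometries overlap. Deterministic for a fixed
    ``spec.seed``; each region uses a sub-seed derived by a fixed offset.
    """
    spec.validate()
    shape = tuple(spec.shape)
    labels = np.zeros(shape, dtype=np.int64)
    for region in spec.regions:
        if region.geometry != "background":
            labels[_region_mask(region, shape)] = region.label

    volume = np.zeros(shape, dtype=np.float64)
    for region in spec.regions:
        rng = np.random.default_rng(spec.seed + 7919 * (region.label + 1))
        mask = labels == region.label
        if not mask.any():
            continue  # fully overwritten by later regions
        tex = region.texture
        pattern = _texture_pattern(tex, shape, mask, rng)
        values = tex.intensity_mean + pattern
        if tex.noise_sd > 0:
            values = values + rng.normal(0.0, tex.noise_sd, shape)
        volume[mask] = values[mask]

    names = [""] * len(spec.regions)
    for r in spec.regions:
        names[r.label] = r.name or f"class_{r.label}"
    return (Volume(np.clip(volume, 0.0, 1.0)),
            LabelVolume(labels, class_names=names))


def _segment_point_distance(p0, p1, q) -> float:
    d = p1 - p0
    t = np.clip(np.dot(q - p0, d) / np.dot(d, d), 0.0, 1.0)
    return float(np.linalg.norm(q - (p0 + t * d)))


def default_phantom_spec(
    shape: tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
    noise_sd: float = 0.02,
    max_attempts: int = 1000,
) -> PhantomSpec:
    """The default four-texture phantom: smooth cytosol background, a
    speckled nucleus ellipsoid, a striped mitochondrion tube and a
    blob-filled granule cluster.

    Region sizes approximate the volume fractions of a cell crop
    (nucleus ~15%, mitochondrion ~6%, granules ~4%, the rest cytosol),
    so the class balance the clustering faces resembles real data.
    Placement uses rejection sampling on centre separations (capped at
    ``max_attempts``); regions may touch, in which case the later region
    in the list takes precedence where they overlap.
    """
    rng = np.random.default_rng(seed)
    shape_f = np.asarray(shape, dtype=np.float64)
    scale = shape_f.min() / 64.0
    nuc_radii = np.array([23.0, 21.0, 19.0]) * scale
    gran_radii = np.array([15.0, 13.0, 12.0]) * scale
    tube_radius = 9.0 * scale

    for _ in range(max_attempts):
        nuc_c = rng.uniform(nuc_radii + 1, shape_f - 2 - nuc_radii)
        gran_c = rng.uniform(gran_radii + 1, shape_f - 2 - gran_radii)
        tube_axis = int(rng.integers(0, 3))
        lo = np.full(3, tube_radius + 1.0)
        hi = shape_f - 2 - tube_radius
        p0 = rng.uniform(lo, hi)
        p1 = p0.copy()
        p0[tube_axis], p1[tube_axis] = lo[tube_axis], hi[tube_axis]
        # partial overlap is allowed (painting precedence resolves it);
        # keep the centres apart so every class keeps a large core
        if (np.linalg.norm(nuc_c - gran_c) > 0.7 * (nuc_radii.max() + gran_radii.max())
                and _segment_point_distance(p0, p1, nuc_c)
                > 0.75 * (nuc_radii.max() + tube_radius)
                and _segment_point_distance(p0, p1, gran_c)
                > 0.8 * (gran_radii.max() + tube_radius)):
            break
    else:
        raise RuntimeError(
            f"could not place phantom regions in {max_attempts} attempts")

    regions = [
        RegionSpec("background", TextureSpec(
            "smooth", intensity_mean=0.75, intensity_contrast=0.0,
            noise_sd=noise_sd), label=0, name="cytosol"),
        RegionSpec("ellipsoid", TextureSpec(
            "speckle", intensity_mean=0.45, intensity_contrast=0.30,
            noise_sd=noise_sd), label=1, name="nucleus",
            center=tuple(nuc_c), radii=tuple(nuc_radii)),
        RegionSpec("tube", TextureSpec(
            "stripes", period=4.0, intensity_mean=0.30,
            intensity_contrast=0.30, noise_sd=noise_sd), label=2,
            name="mitochondria", start=tuple(p0), end=tuple(p1),
            radius=float(tube_radius)),
        RegionSpec("ellipsoid", TextureSpec(
            "blobs", blob_radius=2.5 * scale, intensity_mean=0.60,
            intensity_contrast=0.30, noise_sd=noise_sd), label=3,
            name="granules", center=tuple(gran_c),
            radii=tuple(gran_radii)),
    ]
    return PhantomSpec(shape=shape, regions=regions, seed=seed)


def generate_transformed_pairs(
    volume: Volume,
    labels: LabelVolume,
    n_per_class: int,
    seed: int,
    classes: list[int] | None = None,
    size: float = 8.0,
    rotate: bool = True,
    scale_range: tuple[float, float] = (0.8, 1.25),
    max_translation: float = 2.0,
    strict: bool = True,
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Sample ``n_per_class`` patches per class together with a randomly
    rotated/scaled/translated resampling of the same physical location.

    Used by the transformation-invariance measurement: a good semantic
    representation maps both patches of a pair to nearby points. With
    ``rotate=False``, ``scale_range=(1, 1)``, ``max_translation=0`` the
    transform is the identity and both patches coincide.

    A class with no voxel whose (largest transformed) patch support fits
    inside the volume raises an error naming the class; with
    ``strict=False`` such classes are skipped instead.
    """
    if volume.shape != labels.shape:
        raise ValueError("volume and labels shapes differ")
    rng = np.random.default_rng(seed)
    present = np.unique(labels.data)
    if classes is None:
        classes = [int(c) for c in present]
    margin = math.ceil(size * max(scale_range) * math.sqrt(3) / 2) + 2
    shape = np.asarray(volume.shape)

    pairs = []
    for cls in classes:
        if cls not in present:
            raise ValueError(f"class {cls} absent from labels")
        mask = labels.data == cls
        coords = np.argwhere(mask)
        inside = np.all((coords >= margin) & (coords < shape - margin), axis=1)
        coords = coords[inside]
        if len(coords) == 0:
            if not strict:
                continue   # class too thin for this patch size; skip it
            raise ValueError(
                f"class {cls} has no voxel with full patch support inside the volume")
        picks = coords[rng.integers(0, len(coords), size=n_per_class)]
        for center in picks:
            center = center.astype(np.float64)
            original = extract_patch(volume, SamplingGrid(center=center, size=size))
            offset = (_uniform_ball(rng, max_translation)[0]
                      if max_translation > 0 else np.zeros(3))
            rot = random_rotation(rng) if rotate else np.eye(3)
            new_size = size * rng.uniform(*scale_range)
            transformed = extract_patch(volume, SamplingGrid(
                center=center + offset, size=new_size, rotation=rot))
            pairs.append((original, transformed, int(cls)))
    return pairs
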