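"""Sampling grids, patch extraction and augmentation contracts."""

import numpy as np
import pytest

from voxelrep.sampling import (AugmentationConfig, SamplingGrid,
                               augment_photometric, dense_inference_patches,
                               extract_patch, extract_patches,
                               random_rotation, sample_anchor_grids,
                               sample_positive_grids)
from voxelrep.volume_io import Volume

from oracles import trilinear_point


def test_anchor_grids_count_sizes_and_determinism(rng):
    vol = Volume(np.zeros((24, 24, 24)))
    grids = sample_anchor_grids(vol, 128, (4, 12), np.random.default_rng(7))
    assert len(grids) == 128
    assert all(4 <= g.size <= 12 for g in grids)
    assert all(np.allclose(g.rotation, np.eye(3))
               and np.allclose(g.deformation, np.eye(3)) for g in grids)
    again = sample_anchor_grids(vol, 128, (4, 12), np.random.default_rng(7))
    assert all(np.array_equal(a.center, b.center) and a.size == b.size
               for a, b in zip(grids, again))
    fixed = sample_anchor_grids(vol, 10, (8, 8), rng)
    assert all(g.size == 8 for g in fixed)
    with pytest.raises(ValueError):
        sample_anchor_grids(vol, 0, (4, 12), rng)
    with pytest.raises(ValueError):
        sample_anchor_grids(Volume(np.zeros((8, 8, 8))), 1, (4, 12), rng)


def test_positive_grids_stay_in_ball_and_count(rng):
    anchor = SamplingGrid(center=np.array([12.0, 12.0, 12.0]), size=8.0)
    config = AugmentationConfig(positive_radius=3.0)
    centers = []
    for _ in range(2500):
        for g in sample_positive_grids(anchor, 4, config, rng):
            centers.append(g.center - anchor.center)
    offsets = np.linalg.norm(np.array(centers), axis=1)
    assert len(offsets) == 10000
    assert offsets.max() <= 3.0 + 1e-9
    # mean norm of uniform ball sampling is 3r/4
    assert offsets.mean() == pytest.approx(2.25, rel=0.02)


def test_positive_grids_identity_when_unperturbed(rng):
    anchor = SamplingGrid(center=np.array([10.0, 10.0, 10.0]), size=8.0)
    config = AugmentationConfig(positive_radius=1e-12, rotation="none",
                                deform=0.0, scale_jitter=(1.0, 1.0))
    for g in sample_positive_grids(anchor, 4, config, rng):
        assert np.allclose(g.center, anchor.center, atol=1e-9)
        assert g.size == anchor.size
        assert np.allclose(g.rotation, np.eye(3))
        assert np.allclose(g.deformation, np.eye(3))


def test_random_rotation_matrices_are_rotations(rng):
    for mode in ("full", "axis90"):
        for _ in range(50):
            m = random_rotation(rng, mode)
            assert np.allclose(m @ m.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-12)


def test_extract_patch_exact_on_lattice_aligned_grid():
    rng = np.random.default_rng(0)
    data = rng.random((24, 24, 24))
    vol = Volume(data)
    # 16 points spanning edge length 15 have unit spacing: the patch is
    # exactly the raw 16^3 sub-volume
    grid = SamplingGrid(center=np.array([11.5, 11.5, 11.5]), size=15.0)
    patch = extract_patch(vol, grid)
    assert np.allclose(patch, data[4:20, 4:20, 4:20].astype(np.float32),
                       atol=1e-7)


def test_extract_patch_constant_volume_any_grid(rng):
    vol = Volume(np.full((20, 20, 20), 0.37))
    grid = SamplingGrid(center=np.array([3.0, 10.0, 17.0]), size=11.0,
                        rotation=random_rotation(rng))
    assert np.allclose(extract_patch(vol, grid), 0.37, atol=1e-6)


def test_extract_patch_exact_on_linear_ramp():
    z, y, x = np.meshgrid(*[np.arange(24.0)] * 3, indexing="ij")
    vol = Volume(x / 23.0)
    grid = SamplingGrid(center=np.array([12.0, 12.0, 12.0]), size=8.0)
    coords = grid.coordinates()
    assert np.allclose(extract_patch(vol, grid), coords[2] / 23.0, atol=1e-6)


def test_extract_patch_matches_brute_force_trilinear(rng):
    vol = Volume(rng.random((24, 24, 24)))
    for _ in range(25):
        grid = SamplingGrid(
            center=rng.uniform(9, 15, size=3), size=float(rng.uniform(4, 10)),
            rotation=random_rotation(rng),
            deformation=np.eye(3) + rng.uniform(-0.1, 0.1, (3, 3)))
        patch = extract_patch(vol, grid)
        coords = grid.coordinates().reshape(3, -1)
        idx = rng.integers(0, coords.shape[1], size=40)
        for i in idx:
            want = trilinear_point(vol.data, *coords[:, i])
            assert patch.ravel()[i] == pytest.approx(want, abs=1e-6)


def test_extract_patches_batched_equals_individual(rng):
    vol = Volume(rng.random((24, 24, 24)))
    grids = [SamplingGrid(center=rng.uniform(8, 16, size=3),
                          size=float(rng.uniform(4, 12)),
                          rotation=random_rotation(rng))
             for _ in range(5)]
    batched = extract_patches(vol, grids)
    for i, g in enumerate(grids):
        assert np.array_equal(batched[i], extract_patch(vol, g))


def test_photometric_identity_and_closed_forms(rng):
    identity = AugmentationConfig(brightness=(0.0, 0.0), contrast=(1.0, 1.0),
                                  noise_sd=0.0)
    patch = rng.random((16, 16, 16)).astype(np.float32)
    assert np.allclose(augment_photometric(patch, identity, rng), patch)

    shift = AugmentationConfig(brightness=(0.1, 0.1), contrast=(1.0, 1.0),
                               noise_sd=0.0)
    const = np.full((16, 16, 16), 0.5, dtype=np.float32)
    assert np.allclose(augment_photometric(const, shift, rng), 0.6, atol=1e-6)

    double = AugmentationConfig(brightness=(0.0, 0.0), contrast=(2.0, 2.0),
                                noise_sd=0.0)
    two_level = np.full((16, 16, 16), 0.4, dtype=np.float32)
    two_level[8:] = 0.6
    out = augment_photometric(two_level, double, rng)
    assert np.allclose(out[:8], 0.3, atol=1e-6)
    assert np.allclose(out[8:], 0.7, atol=1e-6)


def test_photometric_output_clipped(rng):
    config = AugmentationConfig(brightness=(0.5, 0.5), contrast=(1.0, 1.0),
                                noise_sd=0.2)
    out = augment_photometric(np.full((16, 16, 16), 0.9, np.float32),
                              config, rng)
    assert out.max() <= 1.0 and out.min() >= 0.0


def test_dense_patches_cover_each_voxel_once():
    vol = Volume(np.random.default_rng(5).random((4, 4, 4)))
    centers, patches = [], []
    for c, p in dense_inference_patches(vol, chunk=(3, 3, 3)):
        centers.append(c)
        patches.append(p)
    centers = np.concatenate(centers)
    assert len(centers) == 64 and sum(len(p) for p in patches) == 64
    unique = {tuple(c) for c in centers}
    assert len(unique) == 64


def test_dense_patches_chunking_transparent():
    vol = Volume(np.random.default_rng(6).random((6, 5, 7)))
    results = {}
    for chunk in [(2, 2, 2), (6, 5, 7), (4, 3, 5)]:
        cs, ps = zip(*dense_inference_patches(vol, chunk=chunk))
        cs, ps = np.concatenate(cs), np.concatenate(ps)
        order = np.lexsort((cs[:, 2], cs[:, 1], cs[:, 0]))
        results[chunk] = ps[order]
    assert np.array_equal(results[(2, 2, 2)], results[(6, 5, 7)])
    assert np.array_equal(results[(2, 2, 2)], results[(4, 3, 5)])


def test_dense_patches_match_trilinear_oracle_with_spacing_8_15():
    rng = np.random.default_rng(7)
    vol = Volume(rng.random((20, 20, 20)))
    target = (10, 10, 10)
    for c, p in dense_inference_patches(vol, chunk=(20, 20, 20)):
        i = np.flatnonzero((c == target).all(axis=1))[0]
        patch = p[i]
    # sample spacing is 8/15 voxels along each axis
    axis = np.linspace(-4.0, 4.0, 16)
    assert np.allclose(np.diff(axis), 8 / 15)
    for (a, b, cc) in [(0, 0, 0), (15, 15, 15), (7, 3, 11)]:
        want = trilinear_point(vol.data, 10 + axis[a], 10 + axis[b],
                               10 + axis[cc])
        assert patch[a, b, cc] == pytest.approx(want, abs=1e-5)
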