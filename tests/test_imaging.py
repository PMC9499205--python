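from collections import deque

import numpy as np
import pytest
import trimesh

from ramusmorph.geometry import ClosestPointQuery
from ramusmorph.imaging import (
    FormatError,
    SeedError,
    fill_mask,
    read_landmarks,
    read_mask,
    read_mesh,
    read_volume,
    reconstruct_surface,
    segment_bone,
    write_landmarks,
    write_mask,
    write_mesh,
    write_volume,
)
from ramusmorph.anatomy import LandmarkSet
from ramusmorph.synthetic import voxelize
from ramusmorph.volume import BinaryMask, VoxelVolume


# ------------------------------------------------------------------ round trips

@pytest.mark.parametrize("suffix", [".nii.gz", ".mha"])
def test_volume_round_trip(tmp_path, rng, suffix):
    vol = VoxelVolume(rng.normal(size=(16, 16, 16)).astype(np.float32), [0.3] * 3, [1.0, -2.0, 0.5])
    path = tmp_path / f"vol{suffix}"
    write_volume(vol, path)
    back = read_volume(path)
    assert back.shape == vol.shape
    assert np.allclose(back.spacing, vol.spacing)
    assert np.allclose(back.origin, vol.origin, atol=1e-5)
    assert np.allclose(back.data, vol.data, atol=1e-6)


def test_mask_round_trip_bit_exact(tmp_path, rng):
    mask = BinaryMask(rng.random((12, 10, 8)) > 0.5, [0.5] * 3, [0, 0, 0])
    write_mask(mask, tmp_path / "m.nii.gz")
    back = read_mask(tmp_path / "m.nii.gz")
    assert np.array_equal(back.data, mask.data)


def test_stl_round_trip_preserves_triangle_count(tmp_path, case_r):
    write_mesh(case_r.preop_mesh, tmp_path / "ramus.stl")
    back = read_mesh(tmp_path / "ramus.stl")
    assert len(back.faces) == len(case_r.preop_mesh.faces)


def test_landmark_round_trip_and_validation(tmp_path):
    lm = LandmarkSet({"C_R": [1.0, 2.0, 3.0], "Go_R": [-4.0, 0.25, 9.5]})
    write_landmarks(lm, tmp_path / "lm.csv")
    back = read_landmarks(tmp_path / "lm.csv")
    assert np.array_equal(back["C_R"], lm["C_R"])

    (tmp_path / "bad.csv").write_text("name,side,x_mm,y_mm,z_mm\nC,R,1.0,,3.0\n")
    with pytest.raises(FormatError):
        read_landmarks(tmp_path / "bad.csv")
    (tmp_path / "cols.csv").write_text("name,x,y\nC,1,2\n")
    with pytest.raises(FormatError):
        read_landmarks(tmp_path / "cols.csv")


# ------------------------------------------------------------------ segmentation

def _flood_fill_26(supra, seed_idx):
    """Brute-force BFS flood fill over 26-connectivity."""
    visited = np.zeros_like(supra, dtype=bool)
    q = deque([tuple(seed_idx)])
    visited[tuple(seed_idx)] = True
    shape = supra.shape
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    while q:
        x, y, z = q.popleft()
        for dx, dy, dz in offsets:
            n = (x + dx, y + dy, z + dz)
            if all(0 <= n[i] < shape[i] for i in range(3)):
                if supra[n] and not visited[n]:
                    visited[n] = True
                    q.append(n)
    return visited


def test_segmentation_keeps_only_the_seeded_blob():
    data = np.zeros((24, 16, 16))
    data[2:8, 4:10, 4:10] = 900.0  # blob A
    data[14:20, 4:10, 4:10] = 900.0  # blob B, disjoint
    vol = VoxelVolume(data, [0.5] * 3, [0, 0, 0])
    seed_world = vol.index_to_world([4, 6, 6])
    mask = segment_bone(vol, seed_world)
    oracle = _flood_fill_26(data >= 226.0, [4, 6, 6])
    assert np.array_equal(mask.data, oracle)
    assert not mask.data[14:20].any()


def test_seed_below_threshold_raises():
    vol = VoxelVolume(np.full((8, 8, 8), 100.0), [0.5] * 3, [0, 0, 0])
    with pytest.raises(SeedError):
        segment_bone(vol, vol.index_to_world([4, 4, 4]))


def test_segmentation_recovers_voxelized_ramus_exactly(case_small):
    vol = case_small.preop_volume
    idx = np.argwhere(vol.data >= 226.0)
    seed = vol.index_to_world(idx[len(idx) // 2])
    mask = segment_bone(vol, seed)
    assert np.array_equal(mask.data, vol.data >= 226.0)


# ------------------------------------------------------------------ cavity fill

def _cavity_oracle(mask):
    """Background components not touching the grid border (6-connectivity)."""
    from scipy import ndimage

    bg_labels, n = ndimage.label(~mask)  # default structure is 6-connected
    touching = set()
    for axis in range(3):
        for sl in (0, -1):
            sel = [slice(None)] * 3
            sel[axis] = sl
            touching.update(np.unique(bg_labels[tuple(sel)]))
    cavity = np.isin(bg_labels, [l for l in range(1, n + 1) if l not in touching])
    return cavity


def test_fill_hollow_sphere_matches_cavity_oracle():
    idx = np.stack(np.meshgrid(*[np.arange(24)] * 3, indexing="ij"), axis=-1)
    r = np.linalg.norm(idx - 11.5, axis=-1)
    shell = (r > 6) & (r < 9)
    mask = BinaryMask(shell, [0.5] * 3, [0, 0, 0])
    filled = fill_mask(mask)
    oracle = shell | _cavity_oracle(shell)
    assert np.array_equal(filled.data, oracle)
    assert filled.count() > mask.count()


def test_fill_is_idempotent():
    data = np.zeros((10, 10, 10), dtype=bool)
    data[3:7, 3:7, 3:7] = True
    mask = BinaryMask(data, [0.5] * 3, [0, 0, 0])
    once = fill_mask(mask)
    twice = fill_mask(once)
    assert np.array_equal(once.data, mask.data)  # already solid
    assert np.array_equal(twice.data, once.data)


# -------------------------------------------------------------- reconstruction

@pytest.fixture(scope="module")
def sphere_mask():
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    vol = voxelize(sphere, spacing_mm=0.3)
    return BinaryMask(vol.data > 400, vol.spacing, vol.origin)


def test_reconstructed_sphere_volume_within_3_percent(sphere_mask):
    mesh = reconstruct_surface(sphere_mask)
    assert mesh.is_watertight
    analytic = 4 / 3 * np.pi * 10.0**3
    assert abs(mesh.volume - analytic) / analytic < 0.03


def test_decimation_reduces_triangles_within_deviation_bound(sphere_mask):
    raw = reconstruct_surface(sphere_mask, decim_iterations=0)
    decimated = reconstruct_surface(sphere_mask)
    assert len(decimated.faces) < len(raw.faces)
    # brute-force deviation of every decimated vertex to the smoothed surface
    query = ClosestPointQuery(raw.vertices, raw.faces)
    _, dev, _ = query.query(decimated.vertices)
    assert dev.max() <= 0.0375 + 1e-9


def test_zero_smoothing_returns_raw_isosurface(sphere_mask):
    from skimage import measure

    mesh = reconstruct_surface(sphere_mask, smooth_iterations=0, smooth_factor=0.0, decim_iterations=0)
    padded = np.pad(sphere_mask.data, 1).astype(np.float32)
    verts, _, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(sphere_mask.spacing))
    verts = verts + (sphere_mask.origin - sphere_mask.spacing)
    assert np.allclose(np.sort(mesh.vertices, axis=0), np.sort(verts, axis=0), atol=1e-6)


def test_sphere_volume_error_decreases_with_spacing():
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    analytic = 4 / 3 * np.pi * 1000.0
    errors = []
    for spacing in (0.6, 0.3, 0.15):
        vol = voxelize(sphere, spacing_mm=spacing)
        mask = BinaryMask(vol.data > 400, vol.spacing, vol.origin)
        mesh = reconstruct_surface(mask, decim_iterations=0)
        errors.append(abs(mesh.volume - analytic) / analytic)
    assert errors[0] > errors[1] > errors[2]


def test_multi_component_mask_rejected():
    data = np.zeros((16, 8, 8), dtype=bool)
    data[1:4, 2:6, 2:6] = True
    data[10:14, 2:6, 2:6] = True
    with pytest.raises(ValueError, match="component"):
        reconstruct_surface(BinaryMask(data, [0.5] * 3, [0, 0, 0]))
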