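"""Volume/mesh/landmark I/O, bone segmentation, and surface reconstruction.

The segmentation chain mirrors a clinical CBCT workflow: seeded threshold
growth at the standard CT bone threshold (226 on the HU-like scale), cavity
filling, then marching-cubes isosurfacing with volume-biased Laplacian
smoothing (10 iterations, factor 0.2) and decimation bounded to a 0.0375 mm
surface deviation.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import trimesh
from scipy import ndimage
from skimage import measure

from .anatomy import LandmarkSet
from .decimate import decimate_mesh
from .volume import BinaryMask, VoxelVolume

__all__ = [
    "FormatError",
    "SeedError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_transform",
    "write_transform",
    "segment_bone",
    "fill_mask",
    "largest_component",
    "reconstruct_surface",
    "BONE_THRESHOLD_HU",
]

#: standard lower threshold for CT bone on the HU-like scale
BONE_THRESHOLD_HU = 226.0


class FormatError(ValueError):
    pass


class SeedError(ValueError):
    pass


# ---------------------------------------------------------------- volume I/O

def write_volume(volume: VoxelVolume, path) -> None:
    path = Path(path)
    if path.suffix == ".mha":
        sitk.WriteImage(volume.to_sitk(), str(path))
        return
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine), str(path))


def read_volume(path) -> VoxelVolume:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    if path.suffix == ".mha":
        return VoxelVolume.from_sitk(sitk.ReadImage(str(path)))
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise FormatError(f"cannot parse volume {path}: {exc}") from exc
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    if np.any(spacing <= 0):
        raise FormatError(f"volume {path} has non-positive spacing {spacing}")
    return VoxelVolume(np.asarray(img.dataobj), spacing, affine[:3, 3])


def write_mask(mask: BinaryMask, path) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(Path(path)))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    data = np.asarray(vol.data)
    if not np.isin(np.unique(data), [0, 1]).all():
        raise FormatError(f"mask {path} has values outside {{0, 1}}")
    return BinaryMask(data > 0, vol.spacing, vol.origin)


# ------------------------------------------------------------------ mesh I/O

def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(str(Path(path)))


def read_mesh(path) -> trimesh.Trimesh:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    loaded = trimesh.load(str(path), process=False)
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise FormatError(f"{path} does not contain a triangle mesh")
    return loaded


# ------------------------------------------------------------- landmark I/O

_LANDMARK_COLUMNS = ["name", "side", "x_mm", "y_mm", "z_mm"]


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    landmarks.to_frame().to_csv(path, index=False)


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"landmark file not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in _LANDMARK_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"landmark CSV {path} is missing columns: {missing}")
    coords = frame[["x_mm", "y_mm", "z_mm"]]
    if coords.isna().any().any():
        bad = frame.loc[coords.isna().any(axis=1), "name"].tolist()
        raise FormatError(f"landmark CSV {path} has missing coordinates for: {bad}")
    return LandmarkSet.from_frame(frame)


# ------------------------------------------------------------ transform I/O

def write_transform(transform, path, **metadata) -> None:
    payload = {"matrix": np.asarray(transform.matrix).reshape(-1).tolist(), **metadata}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_transform(path):
    from .transforms import RigidTransform

    payload = json.loads(Path(path).read_text())
    if "matrix" not in payload or len(payload["matrix"]) != 16:
        raise FormatError(f"transform JSON {path} lacks a 16-element row-major matrix")
    return RigidTransform.from_matrix(np.asarray(payload["matrix"]).reshape(4, 4)), payload


# ------------------------------------------------------------- segmentation

def segment_bone(
    volume: VoxelVolume,
    seed_point,
    lower_threshold_hu: float = BONE_THRESHOLD_HU,
) -> BinaryMask:
    """Connected component (26-connectivity) of supra-threshold voxels
    containing the world-space ``seed_point``."""
    idx = np.round(volume.world_to_index(seed_point)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(volume.shape)):
        raise SeedError(f"seed point {seed_point} is outside the grid")
    if volume.data[tuple(idx)] < lower_threshold_hu:
        raise SeedError(
            f"seed intensity {volume.data[tuple(idx)]:.1f} is below the "
            f"threshold {lower_threshold_hu}"
        )
    supra = volume.data >= lower_threshold_hu
    labels, _ = ndimage.label(supra, structure=np.ones((3, 3, 3), dtype=int))
    return BinaryMask.like(volume, labels == labels[tuple(idx)])


def fill_mask(mask: BinaryMask) -> BinaryMask:
    """Fill interior cavities (background components not reaching the grid
    boundary, 6-connectivity); the exterior is untouched."""
    if mask.count() == 0:
        raise ValueError("cannot fill an empty mask")
    filled = ndimage.binary_fill_holes(mask.data)
    return BinaryMask(filled, mask.spacing, mask.origin)


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Optional noise filter: keep only the largest 26-connected component."""
    labels, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return BinaryMask(labels == np.argmax(counts), mask.spacing, mask.origin)


# ------------------------------------------------------------ reconstruction

def reconstruct_surface(
    mask: BinaryMask,
    smooth_iterations: int = 10,
    smooth_factor: float = 0.2,
    decim_tolerance_mm: float = 0.0375,
    edge_angle_deg: float = 10.0,
    decim_iterations: int = 3,
) -> trimesh.Trimesh:
    """Isosurface -> volume-biased Laplacian smoothing -> bounded decimation.

    ``edge_angle_deg`` limits how far a collapse may rotate a face normal
    (advanced-edge style feature preservation is approximated by the normal
    consistency check of the decimator; the deviation bound is the binding
    constraint).
    """
    if mask.count() == 0:
        raise ValueError("cannot reconstruct an empty mask")
    labels, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        raise ValueError(
            f"mask has {n} connected components; segment and reconstruct per component"
        )
    padded = np.pad(mask.data, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(mask.spacing))
    verts = verts + (mask.origin - mask.spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:  # marching cubes is consistently wound; enforce outward
        mesh.invert()

    if smooth_iterations > 0 and smooth_factor > 0:
        trimesh.smoothing.filter_laplacian(
            mesh, lamb=smooth_factor, iterations=smooth_iterations, volume_constraint=True
        )
    if decim_iterations > 0 and decim_tolerance_mm > 0:
        mesh = decimate_mesh(mesh, tolerance_mm=decim_tolerance_mm, iterations=decim_iterations)
    return mesh
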