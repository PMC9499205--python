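"""Ground-truthed synthetic hemimandible-ramus cases.

The phantom is an implicit-surface composite (ramal plate + posterior border
bulge + condylar neck and head + coronoid process + a parabolic notch bar)
meshed by marching cubes, so that every cephalometric landmark of the analysis
is a well-defined, brute-force-verifiable extremum of the generated surface:
the mandibular-notch C-point is the unique saddle of the superior silhouette,
the gonion a unique posterior-inferior corner extremum, Con/Cor/RP/RI the
extrema of plane cross sections.

A case carries CBCT-like intensities (two-level: background 0, bone 800 on an
HU-like scale, optional Gaussian noise) at 0.30 mm isotropic spacing by
default, a postoperative copy under a known rigid displacement with optional
localized resorption, and seeded observer perturbation of the manual
landmarks.  All generation is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
import trimesh
from skimage import measure

from .anatomy import (
    LandmarkSet,
    locate_c_point,
    locate_derived_landmarks,
    locate_gonion,
)
from .geometry import ClosestPointQuery
from .transforms import RigidTransform, random_rigid
from .volume import VoxelVolume

__all__ = [
    "ShapeParams",
    "ResorptionSpec",
    "SyntheticCase",
    "generate_ramus",
    "apply_remodelling",
    "apply_displacement",
    "simulate_observer",
    "voxelize",
    "save_case",
    "load_case",
    "DEFAULT_SPACING_MM",
    "BONE_INTENSITY",
    "BACKGROUND_INTENSITY",
]

DEFAULT_SPACING_MM = 0.30
BONE_INTENSITY = 800.0
BACKGROUND_INTENSITY = 0.0


# ------------------------------------------------------------------- params

@dataclass(frozen=True)
class ShapeParams:
    """Parametric ramus shape (canonical right side, mm).

    Jitter fractions are the seeded case-to-case anatomical variability; all
    base dimensions are adult-scale ramus measurements.
    """

    body_center: tuple = (-5.5, -23.0, 0.0)
    body_half: tuple = (10.5, 21.0, 2.6)
    body_round: float = 1.5
    bulge_center: tuple = (-16.5, -20.0, 0.0)
    bulge_semi: tuple = (3.4, 16.0, 2.6)
    lower_bulge_center: tuple = (-5.0, -45.5, 0.0)
    lower_bulge_semi: tuple = (9.0, 2.8, 2.6)
    neck_bottom: tuple = (-14.0, -4.0, 0.0)
    neck_top: tuple = (-13.2, 8.0, 0.0)
    neck_radius: float = 3.4
    condyle_center: tuple = (-13.2, 12.5, 0.0)
    condyle_semi: tuple = (4.6, 5.5, 4.3)
    coronoid_center: tuple = (3.2, 6.5, 0.0)
    coronoid_semi: tuple = (4.2, 9.0, 2.3)
    notch_x0: float = -4.5
    notch_y0: float = -1.3
    notch_radius: float = 2.8
    notch_curv_radius: float = 18.0
    notch_span: tuple = (-10.5, 1.5)
    blend_mm: float = 2.0
    shear: float = 0.0
    scale: float = 1.0
    scale_jitter: float = 0.05
    condyle_jitter: float = 0.08
    coronoid_jitter: float = 0.08
    shear_jitter: float = 0.02
    mesh_spacing_mm: float = 0.4
    pose_rotation_deg: float = 6.0
    pose_translation_mm: float = 4.0

    def validate(self) -> None:
        for name in ("body_half", "bulge_semi", "condyle_semi", "coronoid_semi"):
            if min(getattr(self, name)) <= 0:
                raise ValueError(f"shape parameter {name} must be positive")
        for name in ("neck_radius", "notch_radius", "mesh_spacing_mm", "scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"shape parameter {name} must be positive")


@dataclass(frozen=True)
class ResorptionSpec:
    """Localized inward (bone-losing) surface remodelling.

    ``magnitude_mm`` is the maximum inward displacement along vertex normals;
    ``spatial_falloff_mm`` the smoothness scale of the compactly supported
    weight; ``affected_fraction`` the fraction of the target region (by
    distance rank from the region apex) that remodels.
    """

    target_region: str = "condyle"
    magnitude_mm: float = 0.0
    spatial_falloff_mm: float = 3.0
    affected_fraction: float = 0.8

    def validate(self) -> None:
        if self.magnitude_mm < 0:
            raise ValueError("resorption magnitude must be >= 0")
        if self.spatial_falloff_mm <= 0:
            raise ValueError("spatial falloff must be positive")
        if not 0 < self.affected_fraction <= 1:
            raise ValueError("affected fraction must be in (0, 1]")


@dataclass
class SyntheticCase:
    case_id: str
    side: str
    preop_mesh: trimesh.Trimesh
    preop_volume: VoxelVolume | None
    landmarks: LandmarkSet
    reference_markers: trimesh.Trimesh
    seed: int
    shape_params: ShapeParams
    true_displacement: RigidTransform | None = None
    resorption_spec: ResorptionSpec | None = None
    postop_mesh: trimesh.Trimesh | None = None
    postop_volume: VoxelVolume | None = None


# ------------------------------------------------------ signed-distance field

def _sd_rounded_box(p, center, half, radius):
    q = np.abs(p - np.asarray(center)) - np.asarray(half)
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
    inside = np.minimum(np.max(q, axis=1), 0.0)
    return outside + inside - radius


def _sd_ellipsoid(p, center, semi):
    # standard bound-improved approximation; exact enough for meshing
    q = (p - np.asarray(center)) / np.asarray(semi)
    k0 = np.linalg.norm(q, axis=1)
    k1 = np.linalg.norm(q / np.asarray(semi), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.where(k1 > 0, k0 * (k0 - 1.0) / k1, -np.min(semi))
    return sd


def _sd_capsule(p, a, b, radius):
    a = np.asarray(a, dtype=float)
    ab = np.asarray(b, dtype=float) - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - a - t[:, None] * ab, axis=1) - radius


def _sd_polyline_capsule(p, pts, radius):
    d = np.full(len(p), np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        d = np.minimum(d, _sd_capsule(p, a, b, 0.0))
    return d - radius


def _smooth_union(a, b, k):
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b + (a - b) * h - k * h * (1.0 - h)


def _ramus_sdf(points: np.ndarray, sp: ShapeParams) -> np.ndarray:
    p = points.copy()
    p[:, 2] = p[:, 2] - sp.shear * p[:, 1]  # mild lateral bow
    p = p / sp.scale
    d = _sd_rounded_box(p, sp.body_center, sp.body_half, sp.body_round)
    d = _smooth_union(d, _sd_ellipsoid(p, sp.bulge_center, sp.bulge_semi), sp.blend_mm)
    d = _smooth_union(d, _sd_ellipsoid(p, sp.lower_bulge_center, sp.lower_bulge_semi), sp.blend_mm)
    d = _smooth_union(d, _sd_capsule(p, sp.neck_bottom, sp.neck_top, sp.neck_radius), sp.blend_mm)
    d = _smooth_union(d, _sd_ellipsoid(p, sp.condyle_center, sp.condyle_semi), sp.blend_mm)
    d = _smooth_union(d, _sd_ellipsoid(p, sp.coronoid_center, sp.coronoid_semi), sp.blend_mm)
    xs = np.linspace(sp.notch_span[0], sp.notch_span[1], 25)
    arc = np.stack(
        [xs, sp.notch_y0 + (xs - sp.notch_x0) ** 2 / (2 * sp.notch_curv_radius), np.zeros_like(xs)],
        axis=1,
    )
    d = _smooth_union(d, _sd_polyline_capsule(p, arc, sp.notch_radius), sp.blend_mm)
    return d * sp.scale


def _jittered_params(sp: ShapeParams, rng: np.random.Generator) -> ShapeParams:
    def u(j):
        return 1.0 + rng.uniform(-j, j)

    return replace(
        sp,
        scale=sp.scale * u(sp.scale_jitter),
        condyle_semi=tuple(np.asarray(sp.condyle_semi) * u(sp.condyle_jitter)),
        coronoid_semi=tuple(np.asarray(sp.coronoid_semi) * u(sp.coronoid_jitter)),
        shear=sp.shear + rng.uniform(-sp.shear_jitter, sp.shear_jitter),
    )


# --------------------------------------------------------------- generation

def _frankfurt_points(scale: float) -> dict:
    return {
        "Or_R": np.array([32.0, 36.0, 24.0]) * scale,
        "Or_L": np.array([32.0, 36.0, -24.0]) * scale,
        "Po_R": np.array([-34.0, 36.0, 27.0]) * scale,
        "Po_L": np.array([-34.0, 36.0, -27.0]) * scale,
    }


def _marker_mesh(points: dict) -> trimesh.Trimesh:
    spheres = []
    for xyz in points.values():
        s = trimesh.creation.icosphere(subdivisions=2, radius=2.0)
        s.apply_translation(np.asarray(xyz) - np.array([0.0, 2.0, 0.0]))
        spheres.append(s)
    return trimesh.util.concatenate(spheres)


def generate_ramus(
    shape_params: ShapeParams | None = None,
    side: str = "R",
    seed: int = 0,
    voxel_spacing_mm: float = DEFAULT_SPACING_MM,
    with_volume: bool = True,
    noise_sd: float = 0.0,
) -> SyntheticCase:
    """Generate a ground-truthed preoperative ramus case.

    The mesh is extracted by marching cubes from the implicit composite;
    landmarks are then *measured* on that mesh (extremal scans and plane
    sections), never sampled from the analytic model.
    """
    if side not in ("R", "L"):
        raise ValueError(f"side must be 'R' or 'L', got {side!r}")
    sp = shape_params or ShapeParams()
    sp.validate()
    rng = np.random.default_rng(seed)
    sp = _jittered_params(sp, rng)

    # sample the field on a padded canonical grid
    h = sp.mesh_spacing_mm
    lo = np.array([-26.0, -52.0, -9.0]) * sp.scale - 4 * h
    hi = np.array([14.0, 22.0, 9.0]) * sp.scale + 4 * h
    axes = [np.arange(lo[i], hi[i] + h, h) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    sd = _ramus_sdf(grid.reshape(-1, 3), sp).reshape(grid.shape[:3])
    verts, faces, _, _ = measure.marching_cubes(sd, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise RuntimeError("generated ramus mesh is not watertight")

    if side == "L":
        v = mesh.vertices.copy()
        v[:, 2] = -v[:, 2]
        mesh = trimesh.Trimesh(vertices=v, faces=mesh.faces[:, ::-1], process=False)

    # landmarks, measured on the generated mesh (canonical frame: +y superior,
    # -x posterior)
    landmarks = LandmarkSet()
    for name, xyz in _frankfurt_points(sp.scale).items():
        landmarks[name] = xyz
    landmarks[f"C_{side}"] = locate_c_point(mesh, superior=[0.0, 1.0, 0.0])
    landmarks[f"Go_{side}"] = locate_gonion(
        mesh, superior=[0.0, 1.0, 0.0], posterior=[-1.0, 0.0, 0.0]
    )
    landmarks = locate_derived_landmarks(mesh, landmarks, side)
    markers = _marker_mesh(_frankfurt_points(sp.scale))

    # patient pose: a random rigid placement of the whole scene
    pose = random_rigid(
        rng,
        max_translation_mm=sp.pose_translation_mm,
        max_rotation_deg=sp.pose_rotation_deg,
    )
    mesh = apply_displacement(mesh, pose)
    markers = apply_displacement(markers, pose)
    landmarks = landmarks.transformed(pose)

    volume = None
    if with_volume:
        volume = voxelize(mesh, voxel_spacing_mm, noise_sd=noise_sd, seed=seed)
    return SyntheticCase(
        case_id=f"case{seed:04d}{side}",
        side=side,
        preop_mesh=mesh,
        preop_volume=volume,
        landmarks=landmarks,
        reference_markers=markers,
        seed=seed,
        shape_params=sp,
    )


# ------------------------------------------------------------- remodelling

def _region_vertex_mask(case: SyntheticCase, target_region: str) -> np.ndarray:
    from .anatomy import build_planes, partition_ramus
    from .registration import build_reference_structure

    mesh = case.preop_mesh
    if target_region == "reference_structure":
        ref = build_reference_structure(mesh, case.landmarks, case.side)
        face_sel = ref.face_mask
    else:
        planes = build_planes(case.landmarks, case.side)
        labeling = partition_ramus(mesh, planes)
        if target_region not in labeling.region_names:
            raise ValueError(f"unknown target region {target_region!r}")
        face_sel = labeling.face_labels == target_region
    mask = np.zeros(len(mesh.vertices), dtype=bool)
    mask[np.unique(mesh.faces[face_sel])] = True
    return mask


def apply_remodelling(
    case: SyntheticCase, spec: ResorptionSpec, seed: int = 0
) -> trimesh.Trimesh:
    """Displace the target region inward along vertex normals.

    The weight field is compactly supported: it ramps down over
    ``spatial_falloff_mm`` both toward the affected-subset boundary and toward
    the region boundary, so vertices outside the target region move exactly 0
    and enclosed volume never increases.
    """
    spec.validate()
    mesh = case.preop_mesh
    out = mesh.copy()
    if spec.magnitude_mm == 0.0:
        return out
    region = _region_vertex_mask(case, spec.target_region)
    if not region.any():
        raise ValueError(f"target region {spec.target_region!r} selects no vertices")
    v = np.asarray(mesh.vertices)
    normals = np.asarray(mesh.vertex_normals)

    # apex = region vertex farthest from the region boundary's centroid
    boundary = region & np.isin(
        np.arange(len(v)), np.unique(mesh.faces[(region[mesh.faces]).any(axis=1) & ~(region[mesh.faces]).all(axis=1)])
    )
    anchor = v[boundary].mean(axis=0) if boundary.any() else v[region].mean(axis=0)
    ridx = np.nonzero(region)[0]
    d_apex = np.linalg.norm(v[ridx] - v[ridx[np.argmax(np.linalg.norm(v[ridx] - anchor, axis=1))]], axis=1)
    r_aff = np.quantile(d_apex, spec.affected_fraction)
    w = np.clip((r_aff - d_apex) / spec.spatial_falloff_mm, 0.0, 1.0)
    w = w * w * (3.0 - 2.0 * w)  # smoothstep

    # ramp to exactly zero at the region boundary
    if boundary.any():
        d_bound = np.min(
            np.linalg.norm(v[ridx][:, None, :] - v[boundary][None, :, :], axis=2), axis=1
        ) if boundary.sum() < 4000 else None
        if d_bound is None:
            from scipy.spatial import cKDTree

            d_bound, _ = cKDTree(v[boundary]).query(v[ridx])
        ramp = np.clip(d_bound / spec.spatial_falloff_mm, 0.0, 1.0)
        w = w * (ramp * ramp * (3.0 - 2.0 * ramp))

    # mild smooth seeded modulation, kept in (0.85, 1] so the configured
    # magnitude stays the maximum inward displacement
    rng = np.random.default_rng(seed)
    field = np.tanh(rng.normal(size=3) @ (v[ridx] / 10.0).T / np.sqrt(3))
    w = w * (1.0 - 0.075 * (1.0 + field))

    disp = np.zeros_like(v)
    disp[ridx] = -spec.magnitude_mm * w[:, None] * normals[ridx]
    out.vertices = v + disp
    return out


def apply_displacement(obj, transform: RigidTransform):
    """Rigidly displace a mesh (exact vertex map) or a volume (resampled)."""
    if isinstance(obj, trimesh.Trimesh):
        out = obj.copy()
        out.vertices = transform.apply(np.asarray(obj.vertices))
        return out
    if isinstance(obj, VoxelVolume):
        import SimpleITK as sitk

        img = obj.to_sitk()
        inv = transform.inverse()
        t = sitk.AffineTransform(3)
        t.SetMatrix(inv.rotation.reshape(-1))
        t.SetTranslation(inv.translation)
        res = sitk.Resample(img, img, t, sitk.sitkLinear, float(BACKGROUND_INTENSITY))
        return VoxelVolume.from_sitk(res)
    raise TypeError(f"cannot displace object of type {type(obj)!r}")


def make_postop(
    case: SyntheticCase,
    displacement: RigidTransform,
    resorption=None,
    seed: int = 0,
    voxel_spacing_mm: float = DEFAULT_SPACING_MM,
    with_volume: bool = True,
    noise_sd: float = 0.0,
) -> SyntheticCase:
    """Fill the postoperative fields: remodel (one spec or a sequence of
    specs applied in order), displace, re-scan."""
    import dataclasses

    if resorption is None:
        resorption = ResorptionSpec(magnitude_mm=0.0)
    specs = list(resorption) if isinstance(resorption, (list, tuple)) else [resorption]
    post = case.preop_mesh
    staged = dataclasses.replace(case)
    for i, spec in enumerate(specs):
        staged.preop_mesh = post
        post = apply_remodelling(staged, spec, seed=seed + i)
    post = apply_displacement(post, displacement)
    case.true_displacement = displacement
    case.resorption_spec = specs[0] if len(specs) == 1 else tuple(specs)
    case.postop_mesh = post
    if with_volume:
        case.postop_volume = voxelize(post, voxel_spacing_mm, noise_sd=noise_sd, seed=seed + 1)
    return case


# ---------------------------------------------------------------- observers

def simulate_observer(
    case: SyntheticCase,
    perturbation_scale_mm: float,
    seed: int = 0,
    mesh: trimesh.Trimesh | None = None,
    landmarks: LandmarkSet | None = None,
) -> LandmarkSet:
    """Perturb the manual landmarks tangentially on the bone surface.

    Each landmark moves by an isotropic in-tangent-plane Gaussian offset whose
    root-mean-square magnitude equals ``perturbation_scale_mm`` (per-axis
    standard deviation scale/sqrt(2)), then is re-projected onto the surface.
    The reference-structure selection downstream is rebuilt from the perturbed
    landmarks, which jitters the ROI boundary correspondingly.
    """
    if perturbation_scale_mm < 0:
        raise ValueError("perturbation scale must be >= 0")
    mesh = mesh if mesh is not None else case.preop_mesh
    out = (landmarks if landmarks is not None else case.landmarks).copy()
    if perturbation_scale_mm == 0:
        return out
    rng = np.random.default_rng(seed)
    query = ClosestPointQuery(mesh.vertices, mesh.faces)
    sd = perturbation_scale_mm / np.sqrt(2.0)
    from .anatomy import fit_plane_lsq

    frankfurt_n = fit_plane_lsq(
        np.stack([out[n] for n in ("Or_R", "Or_L", "Po_R", "Po_L")])
    ).normal
    for name in list(out.names()):
        base = name.rsplit("_", 1)[0]
        p = out[name]
        g = rng.normal(scale=sd, size=3)
        if base in ("Or", "Po"):
            t = g - (g @ frankfurt_n) * frankfurt_n
            out[name] = p + t
            continue
        if base not in ("C", "Go"):
            continue  # derived landmarks are recomputed per observer
        _, _, fidx = query.query(p)
        n = query.face_normals[fidx[0]]
        t = g - (g @ n) * n
        cp, _, _ = query.query(p + t)
        out[name] = cp[0]
    return out


# -------------------------------------------------------------- voxelization

def voxelize(
    mesh: trimesh.Trimesh,
    spacing_mm: float = DEFAULT_SPACING_MM,
    intensity_model: tuple = (BACKGROUND_INTENSITY, BONE_INTENSITY),
    noise_sd: float = 0.0,
    seed: int = 0,
    margin_mm: float = 3.0,
) -> VoxelVolume:
    """Rasterize a watertight mesh: voxels whose *center* is inside receive
    the bone intensity (exact even-odd parity per slice row), the rest the
    background intensity; optional additive Gaussian noise.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    extent = mesh.bounds[1] - mesh.bounds[0]
    if spacing_mm > extent.min():
        raise ValueError(
            f"spacing {spacing_mm} mm exceeds the smallest mesh extent {extent.min():.3f} mm"
        )
    background, bone = float(intensity_model[0]), float(intensity_model[1])
    lo = mesh.bounds[0] - margin_mm
    # sub-voxel offset decorrelates grid lines from mesh vertices
    origin = lo + spacing_mm * np.array([0.5031, 0.4973, 0.5017])
    shape = np.ceil((mesh.bounds[1] + margin_mm - origin) / spacing_mm).astype(int) + 1
    nx, ny, nz = (int(s) for s in shape)
    xs = origin[0] + np.arange(nx) * spacing_mm
    ys = origin[1] + np.arange(ny) * spacing_mm
    zs = origin[2] + np.arange(nz) * spacing_mm

    tri = np.asarray(mesh.triangles)  # (m, 3, 3)
    tz = tri[:, :, 2]
    tz_min, tz_max = tz.min(axis=1), tz.max(axis=1)
    inside = np.zeros((nx, ny, nz), dtype=bool)

    def slice_segments(zc):
        cand = (tz_min < zc) & (tz_max > zc)
        if not cand.any():
            return None
        t = tri[cand]
        segs = []
        for e0, e1 in ((0, 1), (1, 2), (2, 0)):
            z0, z1 = t[:, e0, 2], t[:, e1, 2]
            cross = (z0 - zc) * (z1 - zc) < 0
            if not cross.any():
                continue
            f = (zc - z0[cross]) / (z1[cross] - z0[cross])
            pt = t[cross, e0, :2] + f[:, None] * (t[cross, e1, :2] - t[cross, e0, :2])
            segs.append((np.nonzero(cross)[0], pt))
        if not segs:
            return None
        # pair the two crossing points of each triangle into one segment
        idx = np.concatenate([s[0] for s in segs])
        if len(idx) % 2 != 0:
            return False  # plane grazes a vertex; caller nudges the slice
        pts = np.concatenate([s[1] for s in segs])
        order = np.argsort(idx, kind="stable")
        return pts[order].reshape(-1, 2, 2)  # (n_seg, endpoint, xy)

    for k, zc in enumerate(zs):
        pts = slice_segments(zc)
        if pts is False:
            pts = slice_segments(zc + 1e-7)
        if pts is None or pts is False:
            continue

        y0, y1 = pts[:, 0, 1], pts[:, 1, 1]
        for j, yc in enumerate(ys):
            rows = (y0 - yc) * (y1 - yc) < 0
            if not rows.any():
                continue
            fr = (yc - y0[rows]) / (y1[rows] - y0[rows])
            xc = pts[rows, 0, 0] + fr * (pts[rows, 1, 0] - pts[rows, 0, 0])
            xc.sort()
            # parity fill between successive crossings
            starts = np.searchsorted(xs, xc[0::2], side="left")
            ends = np.searchsorted(xs, xc[1::2], side="left")
            for s, e in zip(starts, ends):
                inside[s:e, j, k] = True

    data = np.where(inside, bone, background)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(scale=noise_sd, size=data.shape)
    return VoxelVolume(data, np.full(3, spacing_mm), origin)


# ------------------------------------------------------------------- bundle

def save_case(case: SyntheticCase, directory) -> None:
    """Write the on-disk case bundle (STL meshes, NIfTI volumes, landmark CSV,
    ground-truth JSON sidecar)."""
    from .imaging import write_landmarks, write_mesh, write_volume

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_mesh(case.preop_mesh, d / "preop_mesh.stl")
    if case.postop_mesh is not None:
        write_mesh(case.postop_mesh, d / "postop_mesh.stl")
    if case.preop_volume is not None:
        write_volume(case.preop_volume, d / "preop_volume.nii.gz")
    if case.postop_volume is not None:
        write_volume(case.postop_volume, d / "postop_volume.nii.gz")
    write_landmarks(case.landmarks, d / "landmarks.csv")
    truth = {
        "case_id": case.case_id,
        "side": case.side,
        "seed": case.seed,
        "true_displacement": None
        if case.true_displacement is None
        else case.true_displacement.matrix.reshape(-1).tolist(),
        "resorption_spec": None
        if case.resorption_spec is None
        else {
            "target_region": case.resorption_spec.target_region,
            "magnitude_mm": case.resorption_spec.magnitude_mm,
            "spatial_falloff_mm": case.resorption_spec.spatial_falloff_mm,
            "affected_fraction": case.resorption_spec.affected_fraction,
        },
    }
    (d / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def load_case(directory) -> SyntheticCase:
    from .imaging import read_landmarks, read_mesh, read_volume

    d = Path(directory)
    truth = json.loads((d / "ground_truth.json").read_text())
    spec = truth.get("resorption_spec")
    case = SyntheticCase(
        case_id=truth["case_id"],
        side=truth["side"],
        preop_mesh=read_mesh(d / "preop_mesh.stl"),
        preop_volume=read_volume(d / "preop_volume.nii.gz")
        if (d / "preop_volume.nii.gz").exists()
        else None,
        landmarks=read_landmarks(d / "landmarks.csv"),
        reference_markers=trimesh.Trimesh(),
        seed=truth["seed"],
        shape_params=ShapeParams(),
        true_displacement=None
        if truth["true_displacement"] is None
        else RigidTransform.from_matrix(np.asarray(truth["true_displacement"]).reshape(4, 4)),
        resorption_spec=None if spec is None else ResorptionSpec(**spec),
    )
    if (d / "postop_mesh.stl").exists():
        case.postop_mesh = read_mesh(d / "postop_mesh.stl")
    if (d / "postop_volume.nii.gz").exists():
        case.postop_volume = read_volume(d / "postop_volume.nii.gz")
    return case
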