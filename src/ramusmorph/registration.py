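"""The two masked rigid registration engines, run per side.

Both engines align the postoperative (moving) ramus to the preoperative
(fixed) ramus using only the stable reference structure — the coronoid
process plus the ramal band between the mandibular notch and the posterior
border — never the condyle, whose change is the quantity under study.

* surface engine: iterative closest point with point-to-surface
  correspondences and closed-form rigid updates;
* voxel engine: mutual-information maximisation (Mattes estimator, 32 bins)
  over the ROI voxels, multi-resolution, with an explicit
  insufficient-information failure state when the ROI cannot drive the
  metric (the clinically observed failure mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
import trimesh

from .anatomy import LandmarkSet, PlaneSet, build_planes, partition_ramus
from .geometry import ClosestPointQuery
from .transforms import RigidTransform
from .volume import BinaryMask, VoxelVolume

__all__ = [
    "RegistrationError",
    "InsufficientInformationError",
    "ReferenceStructure",
    "RegistrationResult",
    "ICPParams",
    "MIParams",
    "build_reference_structure",
    "reference_roi_mask",
    "prealign",
    "rigid_from_correspondences",
    "icp_register",
    "mi_register",
]


class RegistrationError(RuntimeError):
    pass


class InsufficientInformationError(RegistrationError):
    """The ROI does not contain enough image information to drive the
    intensity metric (too few voxels or near-zero joint entropy)."""


@dataclass
class ReferenceStructure:
    """Face subset of the preoperative mesh (and optional voxel twin) marking
    the anatomy assumed stable for registration."""

    side: str
    face_mask: np.ndarray  # bool per fixed-mesh face
    planes: PlaneSet
    voxel_mask: BinaryMask | None = None
    observer: str = ""

    def vertex_indices(self, mesh) -> np.ndarray:
        return np.unique(np.asarray(mesh.faces)[self.face_mask])


@dataclass
class RegistrationResult:
    transform: RigidTransform
    converged: bool
    final_metric: float
    iterations: int
    method: str
    message: str = ""


@dataclass(frozen=True)
class ICPParams:
    tol_mm: float = 1e-6
    max_iterations: int = 200
    trim_fraction: float = 0.0  # optional robustness; 0 keeps all pairs
    max_vertices: int = 8000  # deterministic stride subsampling of the reference


@dataclass(frozen=True)
class MIParams:
    bins: int = 32
    shrink_factors: tuple = (4, 2, 1)
    smoothing_sigmas: tuple = (2.0, 1.0, 0.0)
    iterations_per_level: int = 100
    learning_rate: float = 1.0
    min_step: float = 1e-4
    min_roi_voxels: int = 500
    min_joint_entropy_bits: float = 1.0
    # mutual information of the joint histogram at the initial alignment;
    # catches a uniform *moving* ROI (e.g. resorbed-away reference bone)
    min_mutual_information_bits: float = 0.1


def _smooth_field(points: np.ndarray, rng: np.random.Generator, wavelength_mm: float = 15.0):
    """A smooth random scalar field with unit-scale amplitude (sum of three
    random plane waves); models the low-frequency freehand variation of a
    manually painted ROI boundary."""
    out = np.zeros(len(points))
    for _ in range(3):
        k = rng.normal(size=3)
        k /= np.linalg.norm(k)
        phase = rng.uniform(0, 2 * np.pi)
        out += np.sin(points @ k * (2 * np.pi / wavelength_mm) + phase)
    return out / np.sqrt(3.0)


def build_reference_structure(
    mesh: trimesh.Trimesh,
    landmarks: LandmarkSet,
    side: str,
    band_fraction: float = 0.6,
    planes: PlaneSet | None = None,
    boundary_jitter_mm: float = 0.0,
    seed: int = 0,
) -> ReferenceStructure:
    """Select the stable reference faces: the coronoid component above the
    C-plane plus the ramal band from the C-plane down to ``band_fraction`` of
    the craniocaudal depth, between the posterior and anterior ramus planes.
    Condylar faces are never included.

    ``boundary_jitter_mm`` displaces the band limits by a seeded smooth random
    field of that amplitude, emulating observer-to-observer variation in the
    freehand ROI selection."""
    landmarks.require(("C", "Con", "Cor", "Go", "RP"), side)
    if planes is None:
        planes = build_planes(landmarks, side)
    labeling = partition_ramus(mesh, planes)
    labels = labeling.face_labels
    centroids = mesh.triangles_center
    ci = planes.ci_coordinate(centroids)
    ap = planes.ap_coordinate(centroids)
    ci_cut = band_fraction * planes.ci_depth
    ap_lo = np.full(len(centroids), -1.0)
    ap_hi = np.full(len(centroids), planes.ap_width + 1.0)
    ci_cut = np.full(len(centroids), ci_cut)
    if boundary_jitter_mm > 0:
        rng = np.random.default_rng(seed)
        ci_cut = ci_cut + boundary_jitter_mm * _smooth_field(centroids, rng)
        ap_lo = ap_lo + boundary_jitter_mm * _smooth_field(centroids, rng)
        ap_hi = ap_hi + boundary_jitter_mm * _smooth_field(centroids, rng)
    band = (
        (labels != "condyle")
        & (labels != "coronoid")
        & (ci <= ci_cut)
        & (ap >= ap_lo)
        & (ap <= ap_hi)
    )
    face_mask = band | (labels == "coronoid")
    if not face_mask.any():
        raise RegistrationError("reference structure selection is empty")
    return ReferenceStructure(side=side, face_mask=face_mask, planes=planes)


def reference_roi_mask(
    reference: ReferenceStructure,
    mesh: trimesh.Trimesh,
    volume: VoxelVolume,
    shell_mm: float = 1.2,
) -> BinaryMask:
    """Voxel twin of the surface selection: voxels whose center lies within
    ``shell_mm`` of the reference surface (covering bone edge and adjacent
    background, which is what drives the intensity metric)."""
    from scipy.spatial import cKDTree

    tri = np.asarray(mesh.triangles)[reference.face_mask]
    # sample each reference triangle at vertices, edge midpoints and centroid
    samples = np.concatenate(
        [
            tri.reshape(-1, 3),
            (0.5 * (tri[:, [0, 1, 2]] + tri[:, [1, 2, 0]])).reshape(-1, 3),
            tri.mean(axis=1),
        ]
    )
    tree = cKDTree(samples)
    lo = samples.min(axis=0) - shell_mm
    hi = samples.max(axis=0) + shell_mm
    lo_idx = np.maximum(np.floor(volume.world_to_index(lo)).astype(int), 0)
    hi_idx = np.minimum(
        np.ceil(volume.world_to_index(hi)).astype(int) + 1, np.asarray(volume.shape)
    )
    data = np.zeros(volume.shape, dtype=bool)
    axes = [
        volume.origin[i] + np.arange(lo_idx[i], hi_idx[i]) * volume.spacing[i] for i in range(3)
    ]
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if len(centers):
        d, _ = tree.query(centers, distance_upper_bound=shell_mm)
        sub = (d <= shell_mm).reshape(
            hi_idx[0] - lo_idx[0], hi_idx[1] - lo_idx[1], hi_idx[2] - lo_idx[2]
        )
        data[lo_idx[0] : hi_idx[0], lo_idx[1] : hi_idx[1], lo_idx[2] : hi_idx[2]] = sub
    roi = BinaryMask(data, volume.spacing.copy(), volume.origin.copy())
    reference.voxel_mask = roi
    return roi


def rigid_from_correspondences(moving_pts, fixed_pts):
    """Closed-form least-squares rigid fit (cross-covariance SVD): returns the
    transform mapping ``moving_pts`` onto ``fixed_pts`` and its RMS residual."""
    m = np.asarray(moving_pts, dtype=float)
    f = np.asarray(fixed_pts, dtype=float)
    if m.shape != f.shape or m.ndim != 2 or m.shape[1] != 3:
        raise RegistrationError("correspondence arrays must both be (n, 3)")
    if len(m) < 3:
        raise RegistrationError(f"need >= 3 point pairs, got {len(m)}")
    mc, fc = m.mean(axis=0), f.mean(axis=0)
    h = (m - mc).T @ (f - fc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(1.0, s[0]):
        raise RegistrationError("correspondences are collinear: rotation is ill-posed")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = fc - rot @ mc
    transform = RigidTransform(rot, t)
    residual = float(np.sqrt(np.mean(np.sum((transform.apply(m) - f) ** 2, axis=1))))
    return transform, residual


def prealign(fixed_landmarks: LandmarkSet, moving_landmarks: LandmarkSet):
    """Landmark-based rigid pre-alignment over the common landmark names."""
    common = [n for n in fixed_landmarks.names() if n in moving_landmarks]
    if len(common) < 3:
        raise RegistrationError(f"need >= 3 paired landmarks, got {len(common)}")
    f = np.stack([fixed_landmarks[n] for n in common])
    m = np.stack([moving_landmarks[n] for n in common])
    return rigid_from_correspondences(m, f)


def icp_register(
    fixed_mesh: trimesh.Trimesh,
    moving_mesh: trimesh.Trimesh,
    reference: ReferenceStructure,
    init: RigidTransform | None = None,
    params: ICPParams = ICPParams(),
) -> RegistrationResult:
    """Masked point-to-surface ICP.

    Fixed reference vertices are matched to their closest points on the
    (currently transformed) moving surface; each iteration applies the
    closed-form rigid update until the mean residual change drops below
    ``tol_mm``.  Deterministic given inputs.
    """
    if int(reference.face_mask.sum()) < 2:
        raise RegistrationError("reference structure must contain more than one face")
    ref_idx = reference.vertex_indices(fixed_mesh)
    if len(ref_idx) < 4:
        raise RegistrationError("reference structure has too few vertices")
    if params.max_vertices and len(ref_idx) > params.max_vertices:
        stride = int(np.ceil(len(ref_idx) / params.max_vertices))
        ref_idx = ref_idx[::stride]
    x = np.asarray(fixed_mesh.vertices, dtype=float)[ref_idx]
    query = ClosestPointQuery(moving_mesh.vertices, moving_mesh.faces)
    transform = init or RigidTransform.identity()

    prev = np.inf
    converged = False
    residual = np.nan
    it = 0
    for it in range(1, params.max_iterations + 1):
        # closest points on the moving surface, expressed in moving coordinates
        q, d, _ = query.query(transform.inverse().apply(x), exact=False)
        xi, qi = x, q
        if params.trim_fraction > 0:
            keep = d <= np.quantile(d, 1.0 - params.trim_fraction)
            if keep.sum() >= 3:
                xi, qi = x[keep], q[keep]
        transform, _ = rigid_from_correspondences(qi, xi)
        residual = float(np.mean(np.linalg.norm(transform.apply(qi) - xi, axis=1)))
        if abs(prev - residual) < params.tol_mm:
            converged = True
            break
        prev = residual
    return RegistrationResult(
        transform=transform,
        converged=converged,
        final_metric=residual,
        iterations=it,
        method="surface",
        message="" if converged else "maximum iterations reached",
    )


def _entropy_bits(hist: np.ndarray) -> float:
    p = hist[hist > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_entropy_bits(fixed_vals, moving_vals, bins):
    h, _, _ = np.histogram2d(fixed_vals, moving_vals, bins=bins)
    return _entropy_bits(h)


def _to_sitk_transform(transform: RigidTransform, center) -> sitk.Euler3DTransform:
    """SimpleITK resampling transforms map fixed-space points into moving
    space, i.e. the inverse of our moving->fixed convention."""
    inv = transform.inverse()
    t = sitk.Euler3DTransform()
    t.SetCenter(tuple(np.asarray(center, dtype=float)))
    t.SetMatrix(tuple(inv.rotation.reshape(-1)))
    center = np.asarray(center, dtype=float)
    # matrix+translation about a center: x -> R (x - c) + c + t
    t.SetTranslation(tuple(inv.rotation @ center - center + inv.translation))
    return t


def _from_sitk_transform(t) -> RigidTransform:
    rot = np.asarray(t.GetMatrix()).reshape(3, 3)
    c = np.asarray(t.GetCenter())
    off = np.asarray(t.GetTranslation())
    full_t = c - rot @ c + off
    return RigidTransform(rot, full_t).inverse()


def mi_register(
    fixed_volume: VoxelVolume,
    moving_volume: VoxelVolume,
    roi_mask: BinaryMask,
    init: RigidTransform | None = None,
    params: MIParams = MIParams(),
) -> RegistrationResult:
    """Masked mutual-information rigid registration (voxel engine).

    Maximises the Mattes mutual information of the ROI voxels of the fixed
    volume against the linearly interpolated moving volume over the six rigid
    degrees of freedom, with a 3-level multi-resolution schedule.  Raises
    :class:`InsufficientInformationError` when the ROI is too small or the
    joint intensity histogram at the initial alignment carries less than the
    minimum entropy — the explicit failure state for uninformative ROIs.
    """
    if not roi_mask.grid_compatible(fixed_volume):
        raise RegistrationError("ROI mask is not on the fixed volume grid")
    n_roi = roi_mask.count()
    if n_roi < params.min_roi_voxels:
        raise InsufficientInformationError(
            f"ROI has {n_roi} voxels (< {params.min_roi_voxels})"
        )
    transform = init or RigidTransform.identity()
    f_img = fixed_volume.to_sitk()
    m_img = moving_volume.to_sitk()
    centers_idx = np.argwhere(roi_mask.data)
    roi_center = fixed_volume.origin + centers_idx.mean(axis=0) * fixed_volume.spacing

    init_t = _to_sitk_transform(transform, roi_center)
    moving_at_init = sitk.GetArrayFromImage(
        sitk.Resample(m_img, f_img, init_t, sitk.sitkLinear, 0.0)
    ).T
    fixed_vals = fixed_volume.data[roi_mask.data]
    moving_vals = moving_at_init[roi_mask.data]
    joint = _joint_entropy_bits(fixed_vals, moving_vals, params.bins)
    hf = _entropy_bits(np.histogram(fixed_vals, bins=params.bins)[0])
    hm = _entropy_bits(np.histogram(moving_vals, bins=params.bins)[0])
    mi0 = hf + hm - joint
    # a clean two-level bone/background ROI legitimately concentrates its
    # joint histogram near 1 bit, so low joint entropy only signals failure
    # when the mutual information is low as well
    if mi0 < params.min_mutual_information_bits or (
        joint < params.min_joint_entropy_bits
        and mi0 < 3 * params.min_mutual_information_bits
    ):
        raise InsufficientInformationError(
            f"mutual information at initialization is {mi0:.3f} bits, joint "
            f"entropy {joint:.3f} bits — not enough mutual image information "
            "in the ROI to constrain the alignment"
        )

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=params.bins)
    reg.SetMetricFixedMask(roi_mask.to_sitk())
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetMetricSamplingStrategy(reg.NONE)  # all ROI voxels: deterministic
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=params.learning_rate,
        minStep=params.min_step,
        numberOfIterations=params.iterations_per_level,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(params.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(params.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(init_t, inPlace=True)
    try:
        final = reg.Execute(sitk.Cast(f_img, sitk.sitkFloat32), sitk.Cast(m_img, sitk.sitkFloat32))
    except RuntimeError as exc:
        return RegistrationResult(
            transform=transform,
            converged=False,
            final_metric=np.nan,
            iterations=0,
            method="voxel",
            message=f"optimizer failure: {exc}",
        )
    stop = reg.GetOptimizerStopConditionDescription()
    return RegistrationResult(
        transform=_from_sitk_transform(sitk.Euler3DTransform(final)),
        converged="Maximum number of iterations" not in stop,
        final_metric=float(reg.GetMetricValue()),
        iterations=int(reg.GetOptimizerIteration()),
        method="voxel",
        message=stop,
    )
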