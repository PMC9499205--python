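import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ramusmorph.anatomy import LandmarkSet
from ramusmorph.registration import (
    ICPParams,
    InsufficientInformationError,
    MIParams,
    RegistrationError,
    build_reference_structure,
    icp_register,
    mi_register,
    prealign,
    reference_roi_mask,
    rigid_from_correspondences,
)
from ramusmorph.synthetic import apply_displacement, voxelize
from ramusmorph.transforms import RigidTransform, random_rigid, rotation_angle_deg
from ramusmorph.volume import BinaryMask, VoxelVolume


@pytest.fixture(scope="module")
def reference_r(case_r):
    return build_reference_structure(case_r.preop_mesh, case_r.landmarks, "R")


# ------------------------------------------------------------------ prealign

def test_prealign_identity(case_r):
    t, residual = prealign(case_r.landmarks, case_r.landmarks)
    assert t.is_identity(1e-9)
    assert residual < 1e-12


def test_prealign_recovers_known_transform(case_r, rng):
    truth = random_rigid(rng, 5.0, 10.0)
    t, residual = prealign(case_r.landmarks, case_r.landmarks.transformed(truth))
    # recovered transform maps moving (displaced) landmarks back onto fixed
    assert np.allclose(t.matrix, truth.inverse().matrix, atol=1e-9)
    assert residual < 1e-9


def test_prealign_needs_three_noncollinear_pairs():
    a = LandmarkSet({"A": [0, 0, 0], "B": [1, 0, 0]})
    with pytest.raises(RegistrationError, match="3"):
        prealign(a, a)
    col = LandmarkSet({"A": [0, 0, 0], "B": [1, 0, 0], "C": [2, 0, 0]})
    with pytest.raises(RegistrationError, match="collinear"):
        prealign(col, col)


def test_kabsch_matches_scipy_align_vectors(rng):
    moving = rng.normal(size=(30, 3)) * 10
    truth = random_rigid(rng, 4.0, 25.0)
    fixed = truth.apply(moving)
    est, residual = rigid_from_correspondences(moving, fixed)
    assert residual < 1e-9
    rot, _ = Rotation.align_vectors(fixed - fixed.mean(0), moving - moving.mean(0))
    assert np.allclose(est.rotation, rot.as_matrix(), atol=1e-8)


# ------------------------------------------------------------------ reference

def test_reference_structure_excludes_condyle(case_r, reference_r, planes_r):
    centroids = case_r.preop_mesh.triangles_center[reference_r.face_mask]
    above = planes_r.c_plane.signed_distance(centroids) > 0
    # any selected face above the C-plane must be coronoid-side (anterior)
    ap = planes_r.ap_coordinate(centroids)
    sep = planes_r.ap_coordinate(planes_r.c_plane.point)[0]
    assert np.all(ap[above] > sep)
    assert reference_r.face_mask.sum() > 100


def test_reference_voxel_twin_agrees_with_surface_selection(case_small):
    """Dice between the ROI mask and an independently computed voxelization
    of the selected surface: rasterize a ball of the shell radius around
    every reference vertex (brute-force local windows, no KD-tree)."""
    shell = 1.4
    ref = build_reference_structure(case_small.preop_mesh, case_small.landmarks, "R")
    roi = reference_roi_mask(ref, case_small.preop_mesh, case_small.preop_volume, shell_mm=shell)
    vol = case_small.preop_volume
    ref_pts = case_small.preop_mesh.vertices[ref.vertex_indices(case_small.preop_mesh)]
    oracle = np.zeros(vol.shape, dtype=bool)
    shape = np.asarray(vol.shape)
    for p in ref_pts:
        lo = np.maximum(np.floor((p - shell - vol.origin) / vol.spacing).astype(int), 0)
        hi = np.minimum(np.ceil((p + shell - vol.origin) / vol.spacing).astype(int) + 1, shape)
        axes = [vol.origin[i] + np.arange(lo[i], hi[i]) * vol.spacing[i] for i in range(3)]
        window = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        close = np.linalg.norm(window - p, axis=-1) <= shell
        oracle[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= close
    overlap = 2 * (oracle & roi.data).sum() / (oracle.sum() + roi.data.sum())
    assert overlap >= 0.9


# ----------------------------------------------------------------------- ICP

def test_icp_identity(case_r, reference_r):
    res = icp_register(case_r.preop_mesh, case_r.preop_mesh, reference_r)
    assert res.converged
    assert np.linalg.norm(res.transform.translation) < 1e-6
    assert rotation_angle_deg(res.transform) < 1e-6


def test_icp_recovers_ground_truth_displacement(case_r, reference_r, rng):
    truth = random_rigid(rng, 5.0, 10.0, center=case_r.preop_mesh.centroid)
    moving = apply_displacement(case_r.preop_mesh, truth)
    init, _ = prealign(case_r.landmarks, case_r.landmarks.transformed(truth))
    perturb = RigidTransform.from_axis_angle(
        [0.2, 1, 0.1], 2.0, [0.8, -0.5, 0.6], center=case_r.preop_mesh.centroid
    )
    res = icp_register(case_r.preop_mesh, moving, reference_r, init=perturb @ init)
    ref_pts = case_r.preop_mesh.vertices[reference_r.vertex_indices(case_r.preop_mesh)]
    tre = np.linalg.norm(
        res.transform.apply(ref_pts) - truth.inverse().apply(ref_pts), axis=1
    ).max()
    assert tre < 0.05


def test_icp_rejects_degenerate_reference(case_r, reference_r):
    import dataclasses

    tiny = dataclasses.replace(reference_r)
    mask = np.zeros_like(reference_r.face_mask)
    mask[np.argmax(reference_r.face_mask)] = True
    tiny.face_mask = mask
    with pytest.raises(RegistrationError):
        icp_register(case_r.preop_mesh, case_r.preop_mesh, tiny)


def test_icp_non_convergence_is_flagged(case_r, reference_r, rng):
    truth = random_rigid(rng, 4.0, 8.0, center=case_r.preop_mesh.centroid)
    moving = apply_displacement(case_r.preop_mesh, truth)
    res = icp_register(
        case_r.preop_mesh, moving, reference_r, params=ICPParams(max_iterations=2)
    )
    assert not res.converged
    assert "iteration" in res.message


def test_icp_equivariance_under_global_rigid_motion(case_r, reference_r, rng):
    """Conjugating fixed and moving by G transforms the recovery to G T G^-1."""
    truth = random_rigid(rng, 3.0, 6.0, center=case_r.preop_mesh.centroid)
    moving = apply_displacement(case_r.preop_mesh, truth)
    init, _ = prealign(case_r.landmarks, case_r.landmarks.transformed(truth))
    base = icp_register(case_r.preop_mesh, moving, reference_r, init=init)

    g = random_rigid(rng, 10.0, 30.0)
    fixed_g = apply_displacement(case_r.preop_mesh, g)
    moving_g = apply_displacement(moving, g)
    init_g = g @ init @ g.inverse()
    res_g = icp_register(fixed_g, moving_g, reference_r, init=init_g)
    expected = g @ base.transform @ g.inverse()
    pts = case_r.preop_mesh.vertices[::50]
    drift = np.linalg.norm(res_g.transform.apply(pts) - expected.apply(pts), axis=1).max()
    assert drift < 1e-3


def test_icp_error_grows_with_reference_remodelling(case_small):
    """When the reference structure itself remodels, the recovered transform
    drifts from ground truth, monotonically in the remodelling magnitude."""
    from ramusmorph.synthetic import ResorptionSpec, apply_remodelling

    truth = RigidTransform.from_axis_angle(
        [0.2, 1.0, 0.1], 4.0, [1.5, -1.0, 0.8], center=case_small.preop_mesh.centroid
    )
    reference = build_reference_structure(case_small.preop_mesh, case_small.landmarks, "R")
    init, _ = prealign(case_small.landmarks, case_small.landmarks.transformed(truth))
    pts = case_small.preop_mesh.vertices[reference.vertex_indices(case_small.preop_mesh)][::7]
    errors = []
    for mag in (0.4, 1.2, 3.0):
        remodelled = apply_remodelling(
            case_small,
            ResorptionSpec("reference_structure", mag, affected_fraction=0.9),
            seed=5,
        )
        moving = apply_displacement(remodelled, truth)
        res = icp_register(
            case_small.preop_mesh, moving, reference, init=init, params=ICPParams(max_iterations=500)
        )
        errors.append(
            float(np.linalg.norm(res.transform.apply(pts) - truth.inverse().apply(pts), axis=1).mean())
        )
    assert errors[0] < errors[1] < errors[2]


# ------------------------------------------------------------------------ MI

@pytest.fixture(scope="module")
def mi_pair(case_small):
    truth = RigidTransform.from_axis_angle(
        [0.1, 0.9, 0.2], 4.0, [1.5, -1.0, 0.8], center=case_small.preop_mesh.centroid
    )
    moving_mesh = apply_displacement(case_small.preop_mesh, truth)
    moving = voxelize(moving_mesh, spacing_mm=0.7)
    ref = build_reference_structure(case_small.preop_mesh, case_small.landmarks, "R")
    roi = reference_roi_mask(ref, case_small.preop_mesh, case_small.preop_volume)
    return case_small, truth, moving, roi


def test_mi_identity(case_small):
    ref = build_reference_structure(case_small.preop_mesh, case_small.landmarks, "R")
    roi = reference_roi_mask(ref, case_small.preop_mesh, case_small.preop_volume)
    res = mi_register(case_small.preop_volume, case_small.preop_volume, roi)
    assert np.linalg.norm(res.transform.translation) < 0.07  # 0.1 voxel at 0.7 mm
    assert rotation_angle_deg(res.transform) < 0.1


def test_mi_recovers_ground_truth(mi_pair):
    case, truth, moving, roi = mi_pair
    init, _ = prealign(case.landmarks, case.landmarks.transformed(truth))
    res = mi_register(case.preop_volume, moving, roi, init=init)
    expected = truth.inverse()
    center = case.preop_mesh.centroid
    assert np.linalg.norm(res.transform.apply(center) - expected.apply(center)) < 0.3
    assert rotation_angle_deg(res.transform, expected) < 0.5


def test_mi_uniform_roi_is_insufficient_information():
    data = np.full((24, 24, 24), 500.0)
    vol = VoxelVolume(data, [0.5] * 3, [0, 0, 0])
    roi = BinaryMask.like(vol, np.ones(vol.shape, dtype=bool))
    with pytest.raises(InsufficientInformationError):
        mi_register(vol, vol, roi)


def test_mi_tiny_roi_rejected(case_small):
    vol = case_small.preop_volume
    data = np.zeros(vol.shape, dtype=bool)
    data[2:4, 2:4, 2:4] = True
    with pytest.raises(InsufficientInformationError, match="voxels"):
        mi_register(vol, vol, BinaryMask.like(vol, data), params=MIParams())
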