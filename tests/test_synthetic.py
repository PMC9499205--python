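import numpy as np
import pytest
import trimesh

from ramusmorph.anatomy import build_planes, partition_ramus
from ramusmorph.geometry import signed_tetra_volume
from ramusmorph.metrics import region_volumes
from ramusmorph.synthetic import (
    ResorptionSpec,
    ShapeParams,
    apply_displacement,
    apply_remodelling,
    generate_ramus,
    load_case,
    make_postop,
    save_case,
    simulate_observer,
    voxelize,
)
from ramusmorph.transforms import NonRigidMatrixError, RigidTransform

COARSE = ShapeParams(mesh_spacing_mm=0.7)


# ---------------------------------------------------------------- generation

def test_same_seed_reproduces_bit_identical_case():
    a = generate_ramus(COARSE, side="R", seed=7, with_volume=False)
    b = generate_ramus(COARSE, side="R", seed=7, with_volume=False)
    assert np.array_equal(a.preop_mesh.vertices, b.preop_mesh.vertices)
    for name in a.landmarks.names():
        assert np.array_equal(a.landmarks[name], b.landmarks[name])


def test_c_point_is_most_caudal_notch_vertex(case_r):
    """Brute-force oracle: scan every vertex, build the superior silhouette
    between the two process peaks, take its lowest arc vertex."""
    mesh = case_r.preop_mesh
    lm = case_r.landmarks
    # superior axis from the (exactly coplanar) Frankfurt markers
    n = np.cross(lm["Or_R"] - lm["Po_R"], lm["Or_L"] - lm["Po_R"])
    n = n / np.linalg.norm(n)
    if (lm["C_R"] - lm["Or_R"]) @ n > 0:
        n = -n
    v = np.asarray(mesh.vertices)
    h = v @ n
    proj = v - np.outer(h, n)
    ctr = proj.mean(axis=0)
    cov = (proj - ctr).T @ (proj - ctr)
    axis = np.linalg.eigh(cov)[1][:, -1]
    u = v @ axis
    # same bin-width rule as the implementation, computed independently
    edges = set()
    for f in mesh.faces:
        for i in range(3):
            edges.add(tuple(sorted((f[i], f[(i + 1) % 3]))))
    lengths = [np.linalg.norm(v[a] - v[b]) for a, b in edges]
    width = max(0.5, 2.5 * float(np.median(lengths)))
    bins = np.floor((u - u.min()) / width).astype(int)
    env = {}
    for i, b in enumerate(bins):  # naive per-bin maximum
        if b not in env or h[i] > h[env[b]]:
            env[b] = i
    order = sorted(env)
    heights = {b: h[env[b]] for b in order}
    peak1 = max(order, key=lambda b: heights[b])
    far = [b for b in order if abs(b - peak1) * width > 6.0]
    peak2 = max(far, key=lambda b: heights[b])
    lo, hi = sorted((peak1, peak2))
    arc = [env[b] for b in order if lo < b < hi]
    c_oracle = v[min(arc, key=lambda i: h[i])]
    assert np.allclose(case_r.landmarks["C_R"], c_oracle, atol=1e-9)


def test_default_volume_spacing_is_030_mm():
    case = generate_ramus(COARSE, side="L", seed=3)
    assert np.allclose(case.preop_volume.spacing, 0.30)


def test_landmarks_lie_on_the_surface(case_r):
    from ramusmorph.geometry import ClosestPointQuery

    query = ClosestPointQuery(case_r.preop_mesh.vertices, case_r.preop_mesh.faces)
    for name in ("C_R", "Go_R", "Con_R", "Cor_R", "RP_R", "RI_R"):
        _, d, _ = query.query(case_r.landmarks[name])
        assert d[0] < 0.3  # within one voxel of the surface


def test_degenerate_shape_params_rejected():
    with pytest.raises(ValueError):
        generate_ramus(ShapeParams(condyle_semi=(0.0, 1.0, 1.0)), seed=1)


# --------------------------------------------------------------- remodelling

@pytest.fixture(scope="module")
def remodel_case():
    return generate_ramus(COARSE, side="R", seed=21, with_volume=False)


def test_zero_magnitude_is_identity(remodel_case):
    post = apply_remodelling(remodel_case, ResorptionSpec("condyle", 0.0), seed=3)
    assert np.array_equal(post.vertices, remodel_case.preop_mesh.vertices)


def test_resorption_volume_loss_is_monotone_in_magnitude(remodel_case):
    vols = []
    for mag in (0.5, 1.0):
        post = apply_remodelling(remodel_case, ResorptionSpec("condyle", mag), seed=3)
        vols.append(signed_tetra_volume(post.vertices, post.faces))
    pre = signed_tetra_volume(remodel_case.preop_mesh.vertices, remodel_case.preop_mesh.faces)
    assert vols[1] < vols[0] < pre


def test_resorption_is_local(remodel_case):
    post = apply_remodelling(remodel_case, ResorptionSpec("condyle", 1.0), seed=3)
    moved = np.linalg.norm(post.vertices - remodel_case.preop_mesh.vertices, axis=1)
    condyle_top = remodel_case.landmarks["Con_R"]
    far = np.linalg.norm(remodel_case.preop_mesh.vertices - condyle_top, axis=1).argmax()
    assert moved[far] == 0.0
    assert moved.max() <= 1.0 + 1e-9  # magnitude is the max inward displacement


def test_unknown_region_rejected(remodel_case):
    with pytest.raises(ValueError, match="unknown target region"):
        apply_remodelling(remodel_case, ResorptionSpec("R99", 0.5), seed=0)


def test_total_volume_loss_decomposes_over_regions(remodel_case):
    """Resorption conservation: whole-mesh loss equals the summed per-region
    losses of the capped solids (same landmarks and planes)."""
    post = apply_remodelling(remodel_case, ResorptionSpec("condyle", 1.0), seed=3)
    planes = build_planes(remodel_case.landmarks, "R")
    labeling = partition_ramus(remodel_case.preop_mesh, planes)
    pre_v = region_volumes(remodel_case.preop_mesh, labeling)
    post_v = region_volumes(post, labeling)
    loss_regions = sum(pre_v[k] - post_v[k] for k in pre_v)
    loss_total = signed_tetra_volume(
        remodel_case.preop_mesh.vertices, remodel_case.preop_mesh.faces
    ) - signed_tetra_volume(post.vertices, post.faces)
    assert loss_regions == pytest.approx(loss_total, rel=1e-3)


# -------------------------------------------------------------- displacement

def test_identity_displacement_preserves_mesh(remodel_case):
    out = apply_displacement(remodel_case.preop_mesh, RigidTransform.identity())
    assert np.allclose(out.vertices, remodel_case.preop_mesh.vertices)


def test_displacement_group_properties(remodel_case, rng):
    from ramusmorph.transforms import random_rigid

    t1 = random_rigid(rng, 5, 20)
    t2 = random_rigid(rng, 5, 20)
    v = remodel_case.preop_mesh.vertices
    seq = apply_displacement(apply_displacement(remodel_case.preop_mesh, t1), t2)
    comp = apply_displacement(remodel_case.preop_mesh, t2 @ t1)
    assert np.allclose(seq.vertices, comp.vertices, atol=1e-9)
    back = apply_displacement(apply_displacement(remodel_case.preop_mesh, t1), t1.inverse())
    assert np.allclose(back.vertices, v, atol=1e-9)


def test_non_rigid_transform_rejected():
    with pytest.raises(NonRigidMatrixError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


# ----------------------------------------------------------------- observers

def test_observer_zero_scale_and_determinism(remodel_case):
    same = simulate_observer(remodel_case, 0.0, seed=4)
    for name in remodel_case.landmarks.names():
        assert np.array_equal(same[name], remodel_case.landmarks[name])
    a = simulate_observer(remodel_case, 0.5, seed=4)
    b = simulate_observer(remodel_case, 0.5, seed=4)
    for name in a.names():
        assert np.array_equal(a[name], b[name])


def test_observer_rms_displacement_matches_scale(remodel_case):
    scale = 0.4
    sq = []
    for i in range(500):
        lm = simulate_observer(remodel_case, scale, seed=i)
        for name in ("C_R", "Go_R"):
            sq.append(np.sum((lm[name] - remodel_case.landmarks[name]) ** 2))
    rms = float(np.sqrt(np.mean(sq)))
    assert abs(rms - scale) / scale < 0.05


# -------------------------------------------------------------- voxelization

def test_voxelized_sphere_volume_within_2_percent():
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    vol = voxelize(sphere, spacing_mm=0.3)
    analytic = 4 / 3 * np.pi * 1000.0
    measured = (vol.data > 400).sum() * vol.voxel_volume_mm3()
    assert abs(measured - analytic) / analytic < 0.02


def test_voxelized_interior_is_single_component():
    from scipy import ndimage

    sphere = trimesh.creation.icosphere(subdivisions=3, radius=6.0)
    vol = voxelize(sphere, spacing_mm=0.4)
    _, n = ndimage.label(vol.data > 400, structure=np.ones((3, 3, 3)))
    assert n == 1


def test_voxelize_rejects_oversized_spacing():
    sphere = trimesh.creation.icosphere(subdivisions=2, radius=2.0)
    with pytest.raises(ValueError, match="spacing"):
        voxelize(sphere, spacing_mm=10.0)


def test_null_change_yields_identical_pre_and_post(case_small):
    """Zero-magnitude resorption plus identity displacement: the
    postoperative mesh and re-scanned volume equal the preoperative ones."""
    import dataclasses

    case = dataclasses.replace(case_small)
    make_postop(
        case,
        RigidTransform.identity(),
        ResorptionSpec("condyle", 0.0),
        voxel_spacing_mm=0.7,
    )
    assert np.array_equal(case.postop_mesh.vertices, case.preop_mesh.vertices)
    assert np.array_equal(case.postop_volume.data, case.preop_volume.data)
    assert np.allclose(case.postop_volume.origin, case.preop_volume.origin)


# -------------------------------------------------------------------- bundle

def test_case_bundle_round_trip(tmp_path, remodel_case):
    import dataclasses

    case = dataclasses.replace(remodel_case)
    case.preop_volume = voxelize(case.preop_mesh, spacing_mm=0.7)
    make_postop(
        case,
        RigidTransform.from_axis_angle([0, 1, 0], 4.0, [1.0, 2.0, -1.0]),
        ResorptionSpec("condyle", 0.5),
        voxel_spacing_mm=0.7,
    )
    save_case(case, tmp_path / "bundle")
    back = load_case(tmp_path / "bundle")
    assert len(back.preop_mesh.faces) == len(case.preop_mesh.faces)
    assert np.allclose(back.true_displacement.matrix, case.true_displacement.matrix)
    assert back.resorption_spec.magnitude_mm == 0.5
    assert back.postop_volume is not None
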