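import numpy as np
import pytest
import trimesh

from ramusmorph.anatomy import (
    AnatomyError,
    LandmarkSet,
    MissingLandmarkError,
    build_planes,
    locate_derived_landmarks,
    partition_ramus,
)
from ramusmorph.geometry import clipped_volume


# ------------------------------------------------------------------- planes

def test_plane_containments_and_parallelisms(case_r, planes_r):
    lm = case_r.landmarks
    assert planes_r.ramus_plane.distance(lm["Go_R"])[0] < 1e-9
    assert planes_r.ramus_plane.distance(lm["Con_R"])[0] < 1e-9
    assert planes_r.ramus_plane.distance(lm["Cor_R"])[0] < 1e-9
    # C-plane parallel to Frankfurt
    dot = abs(planes_r.c_plane.normal @ planes_r.frankfurt.normal)
    assert dot > 1 - 1e-12
    assert planes_r.c_plane.distance(lm["C_R"])[0] < 1e-9
    # posterior plane contains RP and Con, perpendicular to the ramus plane
    assert planes_r.posterior_ramus.distance(lm["RP_R"])[0] < 1e-9
    assert planes_r.posterior_ramus.distance(lm["Con_R"])[0] < 1e-9
    assert abs(planes_r.posterior_ramus.normal @ planes_r.ramus_plane.normal) < 1e-9
    # anterior parallel to posterior, through Cor
    assert abs(planes_r.anterior_ramus.normal @ planes_r.posterior_ramus.normal) > 1 - 1e-12
    assert planes_r.anterior_ramus.distance(lm["Cor_R"])[0] < 1e-9
    # inferior parallel to the C-plane, through RI
    assert abs(planes_r.inferior_ramus.normal @ planes_r.c_plane.normal) > 1 - 1e-12
    assert planes_r.inferior_ramus.distance(lm["RI_R"])[0] < 1e-9


def test_intermediate_planes_equally_spaced(planes_r):
    """Brute-force pairwise plane distances along the shared normal."""
    for planes, bound_a, bound_b in (
        (planes_r.intermediates_ap, planes_r.posterior_ramus, planes_r.anterior_ramus),
        (planes_r.intermediates_ci, planes_r.c_plane, planes_r.inferior_ramus),
    ):
        seq = [bound_a, *planes, bound_b]
        n = seq[0].normal
        offsets = [abs(float((p.point - seq[0].point) @ n)) for p in seq]
        gaps = np.diff(offsets)
        assert np.all(np.abs(gaps - gaps[0]) < 1e-9)


def test_missing_landmark_reports_name(case_r):
    incomplete = LandmarkSet(
        {k: v for k, v in case_r.landmarks.points.items() if k != "RP_R"}
    )
    with pytest.raises(MissingLandmarkError, match="RP_R"):
        build_planes(incomplete, "R")


def test_collinear_ramus_landmarks_rejected(case_r):
    lm = case_r.landmarks.copy()
    direction = lm["Cor_R"] - lm["Con_R"]
    lm["Go_R"] = lm["Con_R"] + 0.37 * direction
    with pytest.raises(AnatomyError, match="collinear|degenerate"):
        build_planes(lm, "R")


# ---------------------------------------------------------------- partition

def test_partition_has_exactly_20_subregions(labeling_r):
    assert len(labeling_r.subregion_names) == 20
    assert labeling_r.region_names[:2] == ["condyle", "coronoid"]


def test_labels_partition_the_whole_surface(case_r, labeling_r):
    areas = case_r.preop_mesh.area_faces
    labeled = sum(
        areas[labeling_r.face_labels == name].sum() for name in labeling_r.region_names
    )
    assert abs(labeled - areas.sum()) / areas.sum() < 1e-6
    # every face has exactly one label
    assert all(l is not None for l in labeling_r.face_labels)


def test_cell_volumes_sum_to_ramal_volume(case_r, planes_r, labeling_r):
    from ramusmorph.metrics import region_volumes

    vols = region_volumes(case_r.preop_mesh, labeling_r)
    cells = sum(v for k, v in vols.items() if k.startswith("R"))
    whole = clipped_volume(
        case_r.preop_mesh.vertices,
        case_r.preop_mesh.faces,
        [(planes_r.c_plane.point, planes_r.c_plane.normal)],
    )
    assert abs(cells - whole) / whole < 1e-3
    # condyle + coronoid account for the remainder
    total = vols["condyle"] + vols["coronoid"] + cells
    assert total == pytest.approx(case_r.preop_mesh.volume, rel=1e-6)


def test_region_adjacency_is_a_4x5_grid(labeling_r):
    for name in labeling_r.subregion_names:
        ap, ci = labeling_r.grid_index(name)
        assert 0 <= ap < 4 and 0 <= ci < 5


def test_condyle_is_posterior_component_above_c_plane(case_r, planes_r, labeling_r):
    centroids = case_r.preop_mesh.triangles_center
    above = planes_r.c_plane.signed_distance(centroids) > 0
    condyle = labeling_r.face_labels == "condyle"
    coronoid = labeling_r.face_labels == "coronoid"
    assert np.array_equal(condyle | coronoid, above)
    ap = planes_r.ap_coordinate(centroids)
    assert ap[condyle].mean() < ap[coronoid].mean()


def test_mirrored_case_yields_mirrored_labeling(case_r, labeling_r):
    mesh = case_r.preop_mesh
    mirror = np.diag([1.0, 1.0, -1.0])
    m2 = trimesh.Trimesh(mesh.vertices @ mirror, mesh.faces[:, ::-1], process=False)
    lm2 = LandmarkSet({k: v @ mirror for k, v in case_r.landmarks.points.items()})
    planes2 = build_planes(lm2, "R")
    lab2 = partition_ramus(m2, planes2)
    # face order is preserved by mirroring, so labels must match face-by-face
    assert np.array_equal(labeling_r.face_labels, lab2.face_labels)


def test_literal_grid_mode_drops_empty_cells(case_r, planes_r):
    lab = partition_ramus(case_r.preop_mesh, planes_r, grid="literal")
    assert 20 <= len(lab.subregion_names) <= 28


# --------------------------------------------------------- derived landmarks

def _manual_only(case):
    keep = ("Or_R", "Or_L", "Po_R", "Po_L", "C_R", "Go_R")
    return LandmarkSet({k: case.landmarks[k] for k in keep})


def test_con_is_posterior_to_cor(case_r, planes_r):
    ax = planes_r.anterior_axis
    assert case_r.landmarks["Con_R"] @ ax < case_r.landmarks["Cor_R"] @ ax


def test_con_matches_brute_force_section_extremum(case_r, planes_r):
    """Exhaustively intersect every triangle with the C-plane and take the
    most posterior crossing point."""
    mesh = case_r.preop_mesh
    n = planes_r.c_plane.normal
    p0 = planes_r.c_plane.point
    best = None
    ax = planes_r.anterior_axis
    for tri in mesh.triangles:
        d = (tri - p0) @ n
        pts = []
        for i in range(3):
            j = (i + 1) % 3
            if (d[i] < 0 <= d[j]) or (d[j] < 0 <= d[i]):
                t = d[i] / (d[i] - d[j])
                pts.append(tri[i] + t * (tri[j] - tri[i]))
        for q in pts:
            if best is None or q @ ax < best @ ax:
                best = q
    assert np.allclose(case_r.landmarks["Con_R"], best, atol=1e-6)


def test_derived_landmarks_are_translation_equivariant(case_r):
    shift = 5.0 * np.array([1.0, 0.0, 0.0])
    mesh2 = case_r.preop_mesh.copy()
    mesh2.vertices = mesh2.vertices + shift
    manual = _manual_only(case_r)
    shifted = LandmarkSet({k: v + shift for k, v in manual.points.items()})
    lm_a = locate_derived_landmarks(case_r.preop_mesh, manual, "R")
    lm_b = locate_derived_landmarks(mesh2, shifted, "R")
    for name in ("Con_R", "Cor_R", "RP_R", "RI_R"):
        assert np.allclose(lm_b[name] - lm_a[name], shift, atol=1e-6)


def test_empty_plane_intersection_raises(case_r):
    manual = _manual_only(case_r)
    manual["C_R"] = manual["C_R"] + np.array([0.0, 500.0, 0.0])  # far above the mesh
    with pytest.raises(AnatomyError):
        locate_derived_landmarks(case_r.preop_mesh, manual, "R")
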