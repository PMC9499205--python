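"""Cephalometric landmark model, cutting planes, and the ramus partition.

The ramus is analysed in a frame derived from the landmarks themselves:

* the Frankfurt plane (least-squares fit to bilateral orbitale/porion points)
  supplies the superior axis;
* the horizontal plane through the mandibular-notch point (C-point), parallel
  to Frankfurt, separates condyle and coronoid process from the ramal body;
* the ramus plane (through Con, Cor, Go) and the posterior/anterior/inferior
  ramus planes bound a grid of equally spaced parallel cutting planes that
  divides the ramal body into 20 subregions (4 anteroposterior x 5
  craniocaudal bands by default).

Landmark names use side suffixes, e.g. ``C_R``, ``Go_L``; the bilateral
Frankfurt landmarks are ``Or_R, Or_L, Po_R, Po_L``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import clipped_volume

__all__ = [
    "AnatomyError",
    "MissingLandmarkError",
    "LandmarkSet",
    "Plane",
    "PlaneSet",
    "RegionLabeling",
    "build_planes",
    "partition_ramus",
    "locate_derived_landmarks",
    "locate_c_point",
    "locate_gonion",
    "fit_plane_lsq",
    "RAMAL_LANDMARK_NAMES",
    "MANUAL_LANDMARK_NAMES",
]

#: the five ramal landmarks that define the cutting-plane grid
RAMAL_LANDMARK_NAMES = ("Con", "Cor", "Go", "RP", "RI")
#: the manual inputs; everything else is derived from the mesh
MANUAL_LANDMARK_NAMES = ("Or", "Po", "C", "Go")

_TABLE_NAMES = ("Or", "Po", "C", "Con", "Cor", "Go", "RP", "RI")


class AnatomyError(ValueError):
    pass


class MissingLandmarkError(AnatomyError):
    pass


class LandmarkSet:
    """Named 3D points in mm, side-suffixed (``name_side``)."""

    def __init__(self, points: dict[str, np.ndarray] | None = None):
        self.points: dict[str, np.ndarray] = {}
        for name, xyz in (points or {}).items():
            self[name] = xyz

    def __setitem__(self, name: str, xyz) -> None:
        xyz = np.asarray(xyz, dtype=float).reshape(3)
        if not np.all(np.isfinite(xyz)):
            raise AnatomyError(f"landmark {name!r} has non-finite coordinates")
        self.points[name] = xyz

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.points:
            raise MissingLandmarkError(f"landmark {name!r} is missing")
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __len__(self) -> int:
        return len(self.points)

    def names(self):
        return list(self.points)

    def get(self, base: str, side: str) -> np.ndarray:
        return self[f"{base}_{side}"]

    def require(self, bases, side: str) -> None:
        missing = [f"{b}_{side}" for b in bases if f"{b}_{side}" not in self.points]
        if missing:
            raise MissingLandmarkError(f"missing landmarks: {', '.join(missing)}")

    def copy(self) -> "LandmarkSet":
        return LandmarkSet({k: v.copy() for k, v in self.points.items()})

    def transformed(self, transform) -> "LandmarkSet":
        return LandmarkSet({k: transform.apply(v) for k, v in self.points.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, xyz in self.points.items():
            base, _, side = name.rpartition("_")
            rows.append({"name": base or name, "side": side, "x_mm": xyz[0], "y_mm": xyz[1], "z_mm": xyz[2]})
        return pd.DataFrame(rows, columns=["name", "side", "x_mm", "y_mm", "z_mm"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LandmarkSet":
        out = cls()
        for _, row in frame.iterrows():
            name = f"{row['name']}_{row['side']}" if str(row["side"]) else str(row["name"])
            out[name] = [row["x_mm"], row["y_mm"], row["z_mm"]]
        return out


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise AnatomyError("plane normal is zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points) -> np.ndarray:
        return (np.atleast_2d(np.asarray(points, dtype=float)) - self.point) @ self.normal

    def distance(self, points) -> np.ndarray:
        return np.abs(self.signed_distance(points))


def fit_plane_lsq(points: np.ndarray) -> Plane:
    """Least-squares plane through >= 3 points (total least squares via SVD)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise AnatomyError("need at least 3 points to fit a plane")
    center = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - center)
    if s[1] < 1e-9:
        raise AnatomyError("plane fit is degenerate (points collinear)")
    return Plane(center, vt[2])


@dataclass
class PlaneSet:
    """The cutting planes of the regional analysis (all normals unit)."""

    frankfurt: Plane
    c_plane: Plane
    ramus_plane: Plane
    posterior_ramus: Plane
    anterior_ramus: Plane
    inferior_ramus: Plane
    intermediates_ap: list = field(default_factory=list)
    intermediates_ci: list = field(default_factory=list)
    superior_axis: np.ndarray = None
    anterior_axis: np.ndarray = None
    side: str = "R"

    @property
    def ap_width(self) -> float:
        """Distance from the posterior to the anterior ramus plane."""
        return float(self.posterior_ramus.signed_distance(self.anterior_ramus.point)[0])

    @property
    def ci_depth(self) -> float:
        """Distance from the C-plane down to the inferior ramus plane."""
        return float(-self.c_plane.signed_distance(self.inferior_ramus.point)[0])

    def ap_coordinate(self, points) -> np.ndarray:
        return self.posterior_ramus.signed_distance(points)

    def ci_coordinate(self, points) -> np.ndarray:
        """Depth below the C-plane (positive inferior)."""
        return -self.c_plane.signed_distance(points)


def _oriented_frankfurt(landmarks: LandmarkSet, side: str) -> tuple[Plane, np.ndarray]:
    for nm in ("Or_R", "Or_L", "Po_R", "Po_L"):
        if nm not in landmarks:
            raise MissingLandmarkError(f"Frankfurt landmark {nm!r} is missing")
    pts = np.stack([landmarks[nm] for nm in ("Or_R", "Or_L", "Po_R", "Po_L")])
    plane = fit_plane_lsq(pts)
    c = landmarks.get("C", side)
    n = plane.normal
    if float((c - plane.point) @ n) > 0:  # ramus lies inferior to Frankfurt
        n = -n
    return Plane(plane.point, n), n


def _mesh_plane_section(mesh, plane: Plane) -> np.ndarray:
    segs = trimesh.intersections.mesh_plane(mesh, plane.normal, plane.point)
    if len(segs) == 0:
        raise AnatomyError("plane does not intersect the mesh")
    return segs.reshape(-1, 3)


def _ap_axis_from_section(section_pts, superior, go, c_point) -> np.ndarray:
    """Principal horizontal direction of the C-plane cross section, oriented
    anterior-positive using the gonion (which lies posterior to the notch)."""
    proj = section_pts - np.outer(section_pts @ superior, superior)
    center = proj.mean(axis=0)
    _, _, vt = np.linalg.svd(proj - center, full_matrices=False)
    axis = vt[0]
    axis = axis - (axis @ superior) * superior
    axis /= np.linalg.norm(axis)
    go_h = go - (go @ superior) * superior
    c_h = c_point - (c_point @ superior) * superior
    if (go_h - c_h) @ axis > 0:  # axis currently points posterior; flip
        axis = -axis
    return axis


def locate_c_point(mesh, superior: np.ndarray, bin_width: float | None = None):
    """Most caudal point of the mandibular-notch arc.

    The notch arc is the superior silhouette between the two superior
    prominences (condylar head and coronoid process): bin vertices along the
    principal horizontal axis, take the most superior vertex per bin, locate
    the two silhouette peaks, and return the lowest arc vertex between them.
    The bin width scales with the mesh's median edge length so that every bin
    spans several vertex columns (isosurface vertices are partly quantized at
    the source grid pitch).
    """
    v = np.asarray(mesh.vertices, dtype=float)
    if bin_width is None:
        edge_v = v[np.asarray(mesh.edges_unique)]
        median_edge = float(np.median(np.linalg.norm(edge_v[:, 0] - edge_v[:, 1], axis=1)))
        bin_width = max(0.5, 2.5 * median_edge)
    superior = np.asarray(superior, dtype=float)
    superior = superior / np.linalg.norm(superior)
    proj = v - np.outer(v @ superior, superior)
    center = proj.mean(axis=0)
    _, _, vt = np.linalg.svd(proj - center, full_matrices=False)
    axis = vt[0]
    u = v @ axis
    h = v @ superior
    bins = np.floor((u - u.min()) / bin_width).astype(int)
    nbins = bins.max() + 1
    env = np.full(nbins, -np.inf)
    env_idx = np.full(nbins, -1, dtype=int)
    order = np.argsort(h)
    env_idx[bins[order]] = order  # last write wins: the highest vertex per bin
    env[bins[order]] = h[order]
    valid = env_idx >= 0
    # condyle/coronoid silhouette peaks: global max, then best peak > 6 mm away
    peak1 = int(np.nanargmax(np.where(valid, env, -np.inf)))
    far = valid & (np.abs(np.arange(nbins) - peak1) * bin_width > 6.0)
    if not far.any():
        raise AnatomyError("could not find two superior prominences")
    peak2 = int(np.argmax(np.where(far, env, -np.inf)))
    lo, hi = sorted((peak1, peak2))
    between = np.arange(lo + 1, hi)
    between = between[valid[between]]
    if len(between) == 0:
        raise AnatomyError("no notch arc between the prominences")
    saddle_bin = between[np.argmin(env[between])]
    return v[env_idx[saddle_bin]].copy()


def locate_gonion(mesh, superior: np.ndarray, posterior: np.ndarray) -> np.ndarray:
    """Most caudal-and-posterior vertex of the mandibular angle (extremum along
    the posterior-inferior diagonal)."""
    direction = np.asarray(posterior, dtype=float) - np.asarray(superior, dtype=float)
    direction = direction / np.linalg.norm(direction)
    v = np.asarray(mesh.vertices, dtype=float)
    return v[int(np.argmax(v @ direction))].copy()


def locate_derived_landmarks(mesh, partial_landmarks: LandmarkSet, side: str) -> LandmarkSet:
    """Complete the landmark set from the manual inputs (Or, Po, C, Go).

    Con/Cor are the extremal points of the C-plane cross-section curve, RP the
    most posterior point of the ramus-plane cross section and RI its most
    inferior point (the ramus plane is the only vertical plane defined at this
    stage; the inferior ramus plane is anchored at the lower ramal border it
    meets there).
    """
    lm = partial_landmarks.copy()
    lm.require(("C", "Go"), side)
    frankfurt, superior = _oriented_frankfurt(lm, side)
    c = lm.get("C", side)
    go = lm.get("Go", side)
    c_plane = Plane(c, superior)
    section = _mesh_plane_section(mesh, c_plane)
    # initial AP direction from the section's principal axis, then refine to
    # the anatomical Con->Cor line until the extrema are self-consistent
    anterior = _ap_axis_from_section(section, superior, go, c)
    con = cor = None
    for _ in range(6):
        ap = section @ anterior
        con_new = section[int(np.argmin(ap))]
        cor_new = section[int(np.argmax(ap))]
        if con is not None and np.array_equal(con_new, con) and np.array_equal(cor_new, cor):
            break
        con, cor = con_new, cor_new
        refined = cor - con
        refined = refined - (refined @ superior) * superior
        anterior = refined / np.linalg.norm(refined)
    n_ramus = np.cross(cor - con, go - con)
    if np.linalg.norm(n_ramus) < 1e-9:
        raise AnatomyError("Con, Cor and Go are collinear: degenerate ramus plane")
    ramus_plane = Plane(con, n_ramus)
    section_r = _mesh_plane_section(mesh, ramus_plane)
    rp = section_r[int(np.argmin(section_r @ anterior))]
    ri = section_r[int(np.argmin(section_r @ superior))]
    for name, xyz in (("Con", con), ("Cor", cor), ("RP", rp), ("RI", ri)):
        lm[f"{name}_{side}"] = xyz
    return lm


def build_planes(
    landmarks: LandmarkSet,
    side: str,
    n_ap_intermediates: int = 3,
    n_ci_intermediates: int = 4,
) -> PlaneSet:
    """Construct the full cutting-plane set from a complete landmark set.

    ``n_ap_intermediates`` interior planes between the posterior and anterior
    ramus planes give ``n_ap_intermediates + 1`` anteroposterior bands;
    likewise craniocaudally between the C-plane and the inferior ramus plane.
    The default 3 x 4 interior planes yield the 4 x 5 = 20 subregion grid.
    """
    landmarks.require(("C", "Con", "Cor", "Go", "RP", "RI"), side)
    frankfurt, superior = _oriented_frankfurt(landmarks, side)
    c = landmarks.get("C", side)
    con = landmarks.get("Con", side)
    cor = landmarks.get("Cor", side)
    go = landmarks.get("Go", side)
    rp = landmarks.get("RP", side)
    ri = landmarks.get("RI", side)

    c_plane = Plane(c, superior)
    n_ramus = np.cross(cor - con, go - con)
    if np.linalg.norm(n_ramus) < 1e-9:
        raise AnatomyError("Con, Cor and Go are collinear: degenerate ramus plane")
    ramus_plane = Plane(con, n_ramus)

    anterior = cor - con
    anterior = anterior - (anterior @ superior) * superior
    anterior /= np.linalg.norm(anterior)

    n_post = np.cross(rp - con, ramus_plane.normal)
    norm = np.linalg.norm(n_post)
    if norm < 1e-9:
        raise AnatomyError("posterior ramus plane is degenerate (RP coincides with Con)")
    n_post = n_post / norm
    if n_post @ anterior < 0:
        n_post = -n_post
    posterior_ramus = Plane(rp, n_post)
    anterior_ramus = Plane(cor, n_post)
    inferior_ramus = Plane(ri, superior)

    width = float(posterior_ramus.signed_distance(cor)[0])
    if width <= 0:
        raise AnatomyError("anterior ramus plane lies posterior to the posterior plane")
    inter_ap = [
        Plane(rp + n_post * (width * k / (n_ap_intermediates + 1)), n_post)
        for k in range(1, n_ap_intermediates + 1)
    ]
    depth = float(-c_plane.signed_distance(ri)[0])
    if depth <= 0:
        raise AnatomyError("inferior ramus plane lies above the C-plane")
    inter_ci = [
        Plane(c - superior * (depth * k / (n_ci_intermediates + 1)), superior)
        for k in range(1, n_ci_intermediates + 1)
    ]
    return PlaneSet(
        frankfurt=frankfurt,
        c_plane=c_plane,
        ramus_plane=ramus_plane,
        posterior_ramus=posterior_ramus,
        anterior_ramus=anterior_ramus,
        inferior_ramus=inferior_ramus,
        intermediates_ap=inter_ap,
        intermediates_ci=inter_ci,
        superior_axis=superior,
        anterior_axis=anterior,
        side=side,
    )


@dataclass
class RegionLabeling:
    """Per-face region labels over {condyle, coronoid, R01..R20} plus the band
    edges needed to rebuild each region's capped solid."""

    face_labels: np.ndarray  # (n_faces,) of str
    planes: PlaneSet
    ap_edges: np.ndarray  # band edges in AP coordinate (mm from posterior plane)
    ci_edges: np.ndarray  # band edges in CI coordinate (mm below C-plane)
    condyle_separating_ap: float  # AP coordinate separating condyle from coronoid

    @functools.cached_property
    def subregion_names(self) -> list:
        return sorted({l for l in self.face_labels if l.startswith("R")})

    @functools.cached_property
    def region_names(self) -> list:
        return ["condyle", "coronoid"] + self.subregion_names

    def grid_index(self, label: str) -> tuple:
        """(ap_band, ci_band) of a subregion label (0-based)."""
        idx = int(label[1:]) - 1
        n_ap = len(self.ap_edges) - 1
        return idx % n_ap, idx // n_ap

    def region_halfspaces(self, label: str) -> list:
        """Clipping half-spaces ``(point, normal)`` whose intersection with the
        mesh solid is the region; outer bands are unbounded outward so the
        cells partition the whole solid."""
        ps = self.planes
        if label in ("condyle", "coronoid"):
            sep_point = ps.posterior_ramus.point + ps.posterior_ramus.normal * self.condyle_separating_ap
            halves = [(ps.c_plane.point, -ps.c_plane.normal)]  # keep above C-plane
            if label == "condyle":
                halves.append((sep_point, ps.posterior_ramus.normal))  # posterior side
            else:
                halves.append((sep_point, -ps.posterior_ramus.normal))
            return halves
        ap_band, ci_band = self.grid_index(label)
        n_ap = len(self.ap_edges) - 1
        n_ci = len(self.ci_edges) - 1
        halves = [(ps.c_plane.point, ps.c_plane.normal)]  # keep below C-plane
        post = ps.posterior_ramus
        if ap_band > 0:
            pt = post.point + post.normal * self.ap_edges[ap_band]
            halves.append((pt, -post.normal))
        if ap_band < n_ap - 1:
            pt = post.point + post.normal * self.ap_edges[ap_band + 1]
            halves.append((pt, post.normal))
        sup = ps.superior_axis
        if ci_band > 0:
            pt = ps.c_plane.point - sup * self.ci_edges[ci_band]
            halves.append((pt, sup))
        if ci_band < n_ci - 1:
            pt = ps.c_plane.point - sup * self.ci_edges[ci_band + 1]
            halves.append((pt, -sup))
        return halves

    def region_volume(self, mesh, label: str) -> float:
        return clipped_volume(mesh.vertices, mesh.faces, self.region_halfspaces(label))


def _face_components(mesh, face_mask: np.ndarray) -> np.ndarray:
    """Connected-component id per selected face (-1 elsewhere)."""
    idx = np.nonzero(face_mask)[0]
    remap = -np.ones(len(mesh.faces), dtype=int)
    remap[idx] = np.arange(len(idx))
    adj = mesh.face_adjacency
    keep = face_mask[adj[:, 0]] & face_mask[adj[:, 1]]
    e = remap[adj[keep]]
    n = len(idx)
    graph = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    out = -np.ones(len(mesh.faces), dtype=int)
    out[idx] = labels
    return out


def partition_ramus(mesh, planes: PlaneSet, grid: str = "default") -> RegionLabeling:
    """Label every face of the ramal surface.

    Faces above the C-plane split into the condylar (posterior) and coronoid
    (anterior) components; faces below are assigned to the anteroposterior x
    craniocaudal grid cell containing their centroid (outer cells absorb the
    slivers beyond the bounding planes, so the labels partition the surface).

    ``grid='literal'`` uses the stated six craniocaudal interior planes (4 x 7
    cells) and drops empty cells; the default grid must have all 20 cells
    nonempty.
    """
    if not mesh.is_watertight:
        raise AnatomyError("partition requires a watertight mesh")
    centroids = mesh.triangles_center
    above = planes.c_plane.signed_distance(centroids) > 0
    if not above.any():
        raise AnatomyError("no faces above the C-plane: C-plane misplaced")

    comp = _face_components(mesh, above)
    n_comp = comp.max() + 1
    areas = mesh.area_faces
    comp_area = np.array([areas[comp == i].sum() for i in range(n_comp)])
    big = np.nonzero(comp_area >= 0.01 * comp_area.sum())[0]
    if len(big) > 2:
        raise AnatomyError(
            f"{len(big)} components above the C-plane (expected condyle + coronoid)"
        )
    ap_c = planes.ap_coordinate(centroids)
    sep_ap = float(planes.ap_coordinate(planes.c_plane.point)[0])
    labels = np.empty(len(mesh.faces), dtype=object)
    if len(big) == 2:
        comp_ap = np.array([ap_c[comp == i].mean() for i in big])
        condyle_comp = big[int(np.argmin(comp_ap))]
        coronoid_comp = big[int(np.argmax(comp_ap))]
        # absorb sliver components into the nearer major component
        mid_ap = float(comp_ap.mean())
        for i in range(n_comp):
            sel = comp == i
            if i == condyle_comp:
                labels[sel] = "condyle"
            elif i == coronoid_comp:
                labels[sel] = "coronoid"
            elif sel.any():
                labels[sel] = "condyle" if ap_c[sel].mean() < mid_ap else "coronoid"
    else:
        # C-plane grazes the notch ridge and the two prominences stay joined:
        # fall back to the vertical plane through the notch point, which is the
        # same separator used for the region solids
        sel = above
        labels[sel] = np.where(ap_c[sel] < sep_ap, "condyle", "coronoid")

    n_ap = 4
    n_ci = 5 if grid == "default" else 7
    width, depth = planes.ap_width, planes.ci_depth
    ap_edges = np.linspace(0.0, width, n_ap + 1)
    ci_edges = np.linspace(0.0, depth, n_ci + 1)

    below = ~above
    ap_band = np.clip(np.floor(ap_c[below] / width * n_ap).astype(int), 0, n_ap - 1)
    ci_band = np.clip(
        np.floor(planes.ci_coordinate(centroids[below]) / depth * n_ci).astype(int),
        0,
        n_ci - 1,
    )
    sub = np.array([f"R{ci * n_ap + ap + 1:02d}" for ap, ci in zip(ap_band, ci_band)], dtype=object)
    labels[below] = sub

    if grid == "default":
        expected = {f"R{i + 1:02d}" for i in range(n_ap * n_ci)}
        present = set(sub)
        if present != expected:
            raise AnatomyError(
                f"empty grid cells under the default configuration: {sorted(expected - present)}"
            )
    return RegionLabeling(
        face_labels=labels,
        planes=planes,
        ap_edges=ap_edges,
        ci_edges=ci_edges,
        condyle_separating_ap=sep_ap,
    )
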