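"""Per-region surface-distance and volumetric discrepancy measures.

The accuracy measure of the whole pipeline is the absolute mean surface
distance between the registered pre- and postoperative rami, evaluated per
anatomical region (condyle, coronoid process, 20 ramal subregions);
volumetric change is the percent difference of the plane-clipped, capped
region solids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .anatomy import RegionLabeling
from .geometry import ClosestPointQuery, clipped_volume

__all__ = [
    "surface_distances",
    "region_accuracy",
    "region_volumes",
    "percent_volume_change",
    "RegionMeasurements",
    "measure_regions",
    "export_distance_map",
    "read_distance_map",
]


def surface_distances(source_mesh: trimesh.Trimesh, target_mesh: trimesh.Trimesh):
    """Signed and absolute distance (mm) from each source vertex to the
    closest point on any target triangle; sign follows the target's outward
    normal (positive outside the target surface)."""
    if len(source_mesh.faces) == 0 or len(target_mesh.faces) == 0:
        raise ValueError("surface distance requires two non-empty meshes")
    query = ClosestPointQuery(target_mesh.vertices, target_mesh.faces)
    signed, absolute, _ = query.signed_distance(np.asarray(source_mesh.vertices))
    return signed, absolute


def region_accuracy(
    labeling: RegionLabeling, mesh: trimesh.Trimesh, abs_distances: np.ndarray
) -> dict:
    """Area-weighted mean absolute surface distance per region (mm).

    ``abs_distances`` is per-vertex on ``mesh`` (the labeled preop mesh);
    faces average their three vertices.  Regions with no faces map to NaN
    (flagged missing, never silently zero)."""
    if len(abs_distances) != len(mesh.vertices):
        raise ValueError("distances are not per-vertex on the labeled mesh")
    face_d = np.asarray(abs_distances)[mesh.faces].mean(axis=1)
    areas = mesh.area_faces
    out = {}
    for name in labeling.region_names:
        sel = labeling.face_labels == name
        if not sel.any():
            out[name] = float("nan")
            continue
        out[name] = float(np.average(face_d[sel], weights=areas[sel]))
    return out


def region_volumes(mesh: trimesh.Trimesh, labeling: RegionLabeling) -> dict:
    """Volume (mm^3) of each region's plane-clipped, capped solid.

    Computed hierarchically (split off the supra-C part, then craniocaudal
    slabs, then anteroposterior cells) so each successive clip acts on a
    shrinking piece; every split conserves volume exactly, so the cells sum
    to the whole solid."""
    from .geometry import clip_soup, soup_volume

    ps = labeling.planes
    sup = ps.superior_axis
    n_post = ps.posterior_ramus.normal
    c_pt = ps.c_plane.point
    tris = np.asarray(mesh.triangles)

    below = clip_soup(tris, c_pt, sup * 1.0)  # keep (x-c)·sup <= 0
    above = clip_soup(tris, c_pt, -sup)
    sep_pt = ps.posterior_ramus.point + n_post * labeling.condyle_separating_ap
    out = {
        "condyle": soup_volume(clip_soup(above, sep_pt, n_post)),
        "coronoid": soup_volume(clip_soup(above, sep_pt, -n_post)),
    }

    n_ap = len(labeling.ap_edges) - 1
    n_ci = len(labeling.ci_edges) - 1
    current = below
    for j in range(n_ci):
        if j < n_ci - 1:
            pt = c_pt - sup * labeling.ci_edges[j + 1]
            slab = clip_soup(current, pt, -sup)  # depth <= edge
            current = clip_soup(current, pt, sup)
        else:
            slab = current
        row = slab
        for i in range(n_ap):
            if i < n_ap - 1:
                pt = ps.posterior_ramus.point + n_post * labeling.ap_edges[i + 1]
                cell = clip_soup(row, pt, n_post)
                row = clip_soup(row, pt, -n_post)
            else:
                cell = row
            name = f"R{j * n_ap + i + 1:02d}"
            if name in {n for n in labeling.region_names}:
                out[name] = soup_volume(cell)
    # any labeled region not covered above (e.g. literal-grid leftovers)
    for name in labeling.region_names:
        if name not in out:
            out[name] = clipped_volume(
                mesh.vertices, mesh.faces, labeling.region_halfspaces(name)
            )
    return out


def percent_volume_change(pre_mm3: float, post_mm3: float) -> float:
    """Signed percent change (post - pre)/pre x 100."""
    if pre_mm3 <= 0:
        raise ValueError("preoperative volume must be positive")
    return (post_mm3 - pre_mm3) / pre_mm3 * 100.0


@dataclass
class RegionMeasurements:
    """Per-region measurement table for one ramus/method/observer."""

    table: pd.DataFrame  # region, preop_volume_mm3, postop_volume_mm3, pct_change, mean_abs_dist_mm, n_faces

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def measure_regions(
    preop_mesh: trimesh.Trimesh,
    registered_postop_mesh: trimesh.Trimesh,
    labeling: RegionLabeling,
    pre_volumes: dict | None = None,
) -> RegionMeasurements:
    """Full regional comparison of a registered pre/post pair.

    Both meshes must already share the preoperative frame; the preoperative
    labeling (planes) indexes both, mirroring the use of preoperative
    landmarks as the only manual input.  ``pre_volumes`` may carry cached
    preoperative region volumes (they do not depend on the registration)."""
    _, abs_d = surface_distances(preop_mesh, registered_postop_mesh)
    acc = region_accuracy(labeling, preop_mesh, abs_d)
    pre_v = pre_volumes if pre_volumes is not None else region_volumes(preop_mesh, labeling)
    post_v = region_volumes(registered_postop_mesh, labeling)
    rows = []
    for name in labeling.region_names:
        sel = labeling.face_labels == name
        rows.append(
            {
                "region": name,
                "preop_volume_mm3": pre_v[name],
                "postop_volume_mm3": post_v[name],
                "pct_change": percent_volume_change(pre_v[name], post_v[name]),
                "mean_abs_dist_mm": acc[name],
                "n_faces": int(sel.sum()),
            }
        )
    return RegionMeasurements(pd.DataFrame(rows))


def export_distance_map(
    mesh: trimesh.Trimesh, distances: np.ndarray, path, clamp_mm: float | None = None
) -> None:
    """Write a color-coded distance map as binary PLY.

    Per-vertex scalars are stored losslessly in a ``distance`` property; the
    color channel uses a symmetric diverging map about 0 (blue = inward,
    white = no change, red = outward), clamped at ``clamp_mm`` (defaults to
    the maximum absolute distance)."""
    distances = np.asarray(distances, dtype=float)
    if len(distances) != len(mesh.vertices):
        raise ValueError("need one distance per vertex")
    import matplotlib

    limit = float(clamp_mm) if clamp_mm else float(np.abs(distances).max()) or 1.0
    normed = np.clip(distances / limit, -1.0, 1.0) * 0.5 + 0.5
    colors = (matplotlib.colormaps["coolwarm"](normed) * 255).astype(np.uint8)
    out = mesh.copy()
    out.visual.vertex_colors = colors
    out.vertex_attributes["distance"] = distances.astype(np.float64)
    out.export(str(path), file_type="ply")


def read_distance_map(path):
    """Recover (mesh, distances) from an exported distance map."""
    mesh = trimesh.load(str(path), process=False)
    raw = mesh.metadata.get("_ply_raw", {})
    try:
        distances = np.asarray(raw["vertex"]["data"]["distance"], dtype=float).ravel()
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path} has no per-vertex distance property") from exc
    return mesh, distances
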