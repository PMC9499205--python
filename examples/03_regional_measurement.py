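"""Measure simulated condylar resorption region by region.

A case with 1 mm condylar resorption and a rigid displacement is registered
on the stable reference structure; the ramus is partitioned into the condyle,
coronoid process and 20 subregions, and per-region volume change and mean
absolute surface distance are computed.  A color-coded distance map is
exported as PLY.
"""

from pathlib import Path

from ramusmorph.anatomy import build_planes, partition_ramus
from ramusmorph.metrics import export_distance_map, measure_regions, surface_distances
from ramusmorph.registration import build_reference_structure, icp_register, prealign
from ramusmorph.synthetic import ResorptionSpec, apply_displacement, generate_ramus, make_postop
from ramusmorph.transforms import RigidTransform

case = generate_ramus(side="L", seed=12, with_volume=False)
truth = RigidTransform.from_axis_angle([0.1, 1.0, 0.0], 5.0, [2.0, -1.0, 1.0],
                                       center=case.preop_mesh.centroid)
make_postop(case, truth, ResorptionSpec(target_region="condyle", magnitude_mm=1.0),
            with_volume=False)

planes = build_planes(case.landmarks, "L")
labeling = partition_ramus(case.preop_mesh, planes)
reference = build_reference_structure(case.preop_mesh, case.landmarks, "L", planes=planes)
init, _ = prealign(case.landmarks, case.landmarks.transformed(truth))
result = icp_register(case.preop_mesh, case.postop_mesh, reference, init=init)
registered = apply_displacement(case.postop_mesh, result.transform)

table = measure_regions(case.preop_mesh, registered, labeling).table
table = table.set_index("region")
print(table[["pct_change", "mean_abs_dist_mm"]].round(3).to_string())
print(f"\ncondyle: {table.loc['condyle', 'pct_change']:.2f}% volume change, "
      f"{table.loc['condyle', 'mean_abs_dist_mm']:.3f} mm mean abs distance "
      "(the resorbed region)")
ramal = table[table.index.str.startswith('R')]["mean_abs_dist_mm"]
print(f"ramal subregions stay near zero: max {ramal.max():.4f} mm "
      "(stable reference, exact registration)")

signed, _ = surface_distances(case.preop_mesh, registered)
Path("scratch").mkdir(exist_ok=True)
export_distance_map(case.preop_mesh, signed, "scratch/distance_map.ply", clamp_mm=1.0)
print("\ncolor-coded distance map written to scratch/distance_map.ply")
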