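"""Compare the surface (ICP) and voxel (mutual information) engines on one
case with a known rigid displacement.

The postoperative scan is the preoperative ramus displaced by a known rigid
transform, so both engines can be scored against ground truth.  Registration
is restricted to the stable reference structure (coronoid + ramal band); the
condyle never drives the alignment.
"""

import numpy as np

from ramusmorph.registration import (
    build_reference_structure,
    icp_register,
    mi_register,
    prealign,
    reference_roi_mask,
)
from ramusmorph.synthetic import generate_ramus, make_postop
from ramusmorph.transforms import RigidTransform, rotation_angle_deg

case = generate_ramus(side="R", seed=3)
truth = RigidTransform.from_axis_angle(
    axis=[0.3, 1.0, 0.2], angle_deg=7.0, translation=[3.0, -2.0, 1.5],
    center=case.preop_mesh.centroid,
)
make_postop(case, truth)  # no remodelling: pure positional change
expected = truth.inverse()  # registration maps postop back onto preop

reference = build_reference_structure(case.preop_mesh, case.landmarks, "R")
init, residual = prealign(case.landmarks, case.landmarks.transformed(truth))
print(f"reference structure: {int(reference.face_mask.sum())} faces; "
      f"landmark prealign residual {residual:.2e} mm")

res_s = icp_register(case.preop_mesh, case.postop_mesh, reference, init=init)
pts = case.preop_mesh.vertices[reference.vertex_indices(case.preop_mesh)]
tre = np.linalg.norm(res_s.transform.apply(pts) - expected.apply(pts), axis=1).max()
print(f"surface engine: converged={res_s.converged} after {res_s.iterations} "
      f"iterations; target registration error {tre:.2e} mm")

roi = reference_roi_mask(reference, case.preop_mesh, case.preop_volume)
res_v = mi_register(case.preop_volume, case.postop_volume, roi, init=init)
center = pts.mean(axis=0)
terr = np.linalg.norm(res_v.transform.apply(center) - expected.apply(center))
rerr = rotation_angle_deg(res_v.transform, expected)
print(f"voxel engine:   converged={res_v.converged} after {res_v.iterations} "
      f"iterations; translation error {terr:.3f} mm, rotation error {rerr:.3f} deg")
print("\nboth errors are far below the 0.30 mm voxel size: with no "
      "remodelling, either engine recovers the positional change.")
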