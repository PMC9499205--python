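"""Demonstrate the voxel engine's explicit insufficient-information failure.

When the reference band itself resorbs severely, the region of interest in
the postoperative scan contains almost no bone and the joint intensity
histogram carries too little mutual information to drive the metric.  The
voxel engine refuses with an explicit error (rather than silently returning
a wrong alignment); the surface engine still completes.
"""

from ramusmorph.registration import (
    ICPParams,
    InsufficientInformationError,
    build_reference_structure,
    icp_register,
    mi_register,
    prealign,
    reference_roi_mask,
)
from ramusmorph.synthetic import ResorptionSpec, ShapeParams, generate_ramus, make_postop
from ramusmorph.transforms import RigidTransform

case = generate_ramus(ShapeParams(mesh_spacing_mm=0.6), side="R", seed=42,
                      voxel_spacing_mm=0.6)
truth = RigidTransform.from_axis_angle([0, 1, 0], 4.0, [2.0, -1.0, 0.5],
                                       center=case.preop_mesh.centroid)
make_postop(
    case,
    truth,
    ResorptionSpec(target_region="reference_structure", magnitude_mm=6.0,
                   spatial_falloff_mm=2.0, affected_fraction=1.0),
    voxel_spacing_mm=0.6,
)

reference = build_reference_structure(case.preop_mesh, case.landmarks, "R")
init, _ = prealign(case.landmarks, case.landmarks.transformed(truth))

res = icp_register(case.preop_mesh, case.postop_mesh, reference, init=init,
                   params=ICPParams(max_iterations=500))
print(f"surface engine: converged={res.converged}, residual "
      f"{res.final_metric:.2f} mm (biased by the remodelling, but usable)")

roi = reference_roi_mask(reference, case.preop_mesh, case.preop_volume)
try:
    mi_register(case.preop_volume, case.postop_volume, roi, init=init)
    print("voxel engine: completed (unexpected for this severity)")
except InsufficientInformationError as exc:
    print(f"voxel engine: explicit failure -> {exc}")
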