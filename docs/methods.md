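# Methods

`ramusmorph` implements a long-term three-dimensional assessment of condylar
remodelling after orthognathic surgery: rigid registration of pre- and
postoperative rami restricted to a stable anatomical reference structure,
landmark-derived partition of each ramus into anatomical regions, per-region
surface-distance and volume-change measures, and reliability statistics
comparing two registration engines and two observers.  Because no clinical
images are distributed, every quantitative claim in the test suite is made on
ground-truthed synthetic phantoms generated by the package itself.  This note
records the models, defaults and numerical choices.

## Coordinate conventions

All geometry lives in a right-handed millimetre frame.  Volumes are
axis-aligned scalar grids with `world = origin + index * spacing` (no
direction matrix).  The anatomical directions are defined by the landmarks,
never by the world axes: *superior* is the Frankfurt-plane normal (oriented
away from the ramus), *anterior* the in-plane direction from the condylar
(Con) to the coronoid (Cor) landmark.  Rigid transforms are
rotation-plus-translation pairs `x -> R x + t` with `det R = +1` enforced to
1e-6; registration transforms map the moving (postoperative) frame onto the
fixed (preoperative) frame.

## Synthetic ramus phantom

The phantom is an implicit-surface composite meshed by marching cubes: a
rounded ramal plate, a posterior-border bulge (so the most posterior ramal
point RP is a unique extremum), a gently bowed lower border (so the most
inferior point RI is unique), a condylar neck and ellipsoidal head, an
elongated coronoid process, and a parabolic "notch bar" joining neck and
coronoid whose circular cross-section makes the mandibular-notch saddle
(C-point) a unique, brute-force-verifiable extremum.  Smooth unions (blend
2 mm) keep the surface C1 almost everywhere; the default meshing pitch is
0.4 mm and every generated mesh is watertight by construction.

Landmarks are *measured on the generated mesh*, not copied from the analytic
model: the C-point by a superior-silhouette scan (bin width 2.5x the median
edge length, guarding against grid-pitch aliasing of isosurface vertices),
the gonion as the posterior-inferior diagonal extremum, and Con/Cor/RP/RI as
extrema of plane cross sections via the same `locate_derived_landmarks`
routine the analysis pipeline uses.  The orbitale and porion landmarks that
define the Frankfurt plane have no skull to sit on; they are placed on small
auxiliary marker spheres rigidly attached to the case (a deliberate
synthetic-scene device).  Each case receives a random rigid "patient pose"
(<= 6 degrees, <= 4 mm) so no plane is axis-aligned, and seeded anatomical
jitter (global scale +-5%, condyle/coronoid axes +-8%, lateral shear
+-0.02).  All generation is a pure function of (parameters, seed).

Volumes are two-level CBCT-like rasterizations: voxels whose centre lies
inside the mesh (exact even-odd parity per slice row) receive 800 on an
HU-like scale, background 0, at 0.30 mm isotropic spacing by default;
Gaussian noise is available but defaults to 0 because on an uncalibrated
CBCT-like scale only threshold separability matters.  The bone level sits
well above the standard 226 bone threshold used by segmentation.

Resorption is modelled as inward displacement along vertex normals with a
compactly supported smooth weight: within the target region an
`affected_fraction` quantile ball around the region apex carries weight 1,
ramping to 0 over `spatial_falloff_mm` both toward the ball boundary and
toward the region boundary, times a mild seeded smooth modulation in
(0.85, 1].  The configured magnitude is therefore the maximum inward
displacement, volume never increases, and vertices outside the region move
exactly zero.  The literature gives no quantitative remodelling model, so
magnitudes are free parameters; the cohort default of 1.0 mm condylar
resorption produces roughly 25-35% condylar volume loss on this geometry,
and no clinical severity scale is claimed.

Observer variability has two components, both seeded: (i) manual landmarks
(orbitale, porion, C-point, gonion) are displaced tangentially on the bone
surface by an isotropic in-plane Gaussian whose RMS magnitude is the
configured scale (default 0.5 mm), then re-projected onto the surface;
(ii) the freehand reference-ROI boundary is jittered by a smooth random
field (three random plane waves, 15 mm wavelength) of amplitude
`roi_jitter_mm` (default 2 mm), reflecting that painting a mask boundary is
far less reproducible than clicking a point.  Derived landmarks and planes
are recomputed per observer from the perturbed manual inputs, so partition
and ROI differences propagate exactly as they would clinically.

## Segmentation and surface reconstruction

Segmentation is seeded threshold growth: the 26-connected component of
voxels at or above 226 (HU-like) containing the seed, followed by cavity
filling (6-connected background components not reaching the grid border).
The commercial "bone wizard" growing sensitivity is proprietary and is not
reproduced.  Reconstruction is marching cubes on the (padded) mask, then
volume-biased Laplacian smoothing (10 iterations, factor 0.2), then
edge-collapse decimation with a bounded deviation: a collapse is accepted
only if the manifold link condition holds, no incident face flips, and the
collapse midpoint lies within half the tolerance (default 0.0375 mm) of the
original surface.  For smooth surfaces the midpoint deviation and the
removed-vertex deviation scale identically (edge^2/curvature radius), so the
two-sided deviation stays within the tolerance; the suite verifies the
vertex-to-original-surface bound by brute force.  Decimation preserves
watertightness by construction.

## Registration engines

Both engines are masked to the stable reference structure: the coronoid
process plus the ramal band from the notch plane down to 60% of the
craniocaudal depth, between the posterior and anterior ramus planes.  The
condyle — the structure whose change is measured — never drives the
alignment.

*Surface engine.*  Point-to-surface ICP: the fixed reference vertices (at
most 8000, deterministic stride) are matched to their closest points on the
currently transformed moving surface, followed by a closed-form
(cross-covariance SVD) rigid update, until the mean residual changes by less
than 1e-6 mm or 200 iterations.  Closest points come from an exact KD-tree
candidate search; during ICP the exactness radius-pass is skipped (nearest
of 8 candidate faces), which is ample for correspondence search.  No outlier
trimming by default; a trim fraction is exposed.

*Voxel engine.*  Mutual-information maximisation over the 6 rigid degrees of
freedom via SimpleITK: Mattes estimator with 32 histogram bins, all voxels
of the fixed ROI (no stochastic sampling, hence deterministic),
regular-step gradient descent with physical-shift scales, three resolution
levels (shrink 4/2/1, smoothing 2/1/0 voxels).  The ROI voxel mask is the
shell of voxels within 1.2 mm of the selected reference surface, covering
the bone boundary and adjacent background.  Before optimising, the engine
computes the joint histogram at the initial alignment and raises an explicit
insufficient-information failure when the ROI has fewer than 500 voxels or
the mutual information at initialisation is below 0.1 bits (a
low-joint-entropy branch additionally flags degenerate histograms).  The
mutual-information gate is the binding one: a clean two-level
bone/background ROI legitimately concentrates its joint histogram near
1 bit of entropy, while the clinically observed failure mode — reference
bone resorbed away, moving ROI nearly uniform — drives the mutual
information to zero.  Failures are states to be reported, never
silent wrong alignments.

Initialisation is closed-form landmark pre-alignment (centred Kabsch), with
the ROI centroid as rotation centre for the voxel engine.

## Anatomy: planes and partition

The Frankfurt plane is the total-least-squares plane through the four
orbitale/porion points; the C-plane passes through the C-point parallel to
it.  The ramus plane passes through Con, Cor and Go; the posterior ramus
plane contains RP and Con and is perpendicular to the ramus plane; the
anterior ramus plane is its parallel through Cor; the inferior ramus plane
passes through RI parallel to the C-plane.  Derived landmarks are located
iteratively: Con/Cor start as extrema along the section's principal axis
and are refined along the Con-to-Cor direction until self-consistent, which
removes the axis-tilt sensitivity of a one-shot PCA.  The source protocol
references an undefined "V1 plane" for RI; here RI is the most inferior
point of the ramus-plane cross section, which anchors the inferior plane at
the lower ramal border and lets the craniocaudal grid span the whole ramus.

The stated interior-plane counts (three anteroposterior, six craniocaudal)
are arithmetically inconsistent with the stated total of 20 subregions
(they would give 4 x 7 = 28 cells); the default grid treats the craniocaudal
count as including the two bounding planes, i.e. four interior planes and
4 x 5 = 20 cells, all of which must be nonempty.  A `grid="literal"` mode
builds the 4 x 7 grid and drops empty cells.  Faces above the C-plane split
into condyle (posterior connected component) and coronoid (anterior); when
the C-plane grazes the notch ridge and the components stay joined, the
vertical plane through the C-point — the same separator used for the region
solids — is the fallback.  Faces below the C-plane are assigned to the grid
cell containing their centroid, with the outer bands absorbing slivers
beyond the bounding planes so the labels exactly partition the surface.

Region volumes use plane-clipped, capped solids: clipping collects the
directed boundary edges on the cut plane and closes them with a signed fan,
which is exact for the divergence-theorem volume even for non-convex cross
sections; splits conserve volume to machine precision, so the 20 cells sum
to the ramal solid (the suite requires 0.1%, observed ~1e-13 relative).
Volumes are computed hierarchically (supra-C part, then craniocaudal slabs,
then anteroposterior cells) for speed; a generic per-region half-space path
cross-checks it.

## Measures and statistics

Surface discrepancy is the distance from each preoperative vertex to the
closest point on any registered postoperative triangle (exact, not nearest
vertex), signed by the target's outward normal; the accuracy measure is the
area-weighted mean absolute distance per region (area weighting is robust to
the non-uniform triangulation left by decimation).  Volume change is
reported signed, `(post - pre)/pre x 100`, with absolute values used in MAD
summaries.  Distance maps are exported as binary PLY with a lossless
per-vertex scalar and a symmetric diverging colour scale.

Reliability is ICC(1,1) — one-way random effects, single measures — computed
from the ANOVA mean squares with exact F-based 95% confidence bounds, plus
the mean absolute difference between observers and the standard deviation of
those absolute differences.  Method comparisons use the classical two-sided
paired t per region, pairing by ramus, with no multiplicity correction
(matching the per-region reporting convention; a Holm option would be a
one-line addition but is deliberately absent by default).  ICC
classification defaults to the 0.5/0.75/0.9 convention; alternative
threshold sets can be supplied, since published reports sometimes label the
0.82-1.00 range excellent.

## Study conditions and problem sizes

The cohort experiment mirrors the study design: 20 rami (alternating sides),
half with 1.0 mm condylar resorption, mild 0.25 mm remodelling of the
reference band everywhere (long-term change does not spare the reference
structures entirely — this is also what makes interobserver error grow with
distance from the ROI), displacement up to 4 mm / 6 degrees, two observers
at 0.5 mm landmark scale and 2 mm ROI-boundary jitter.  Desk-scale problem
sizes chosen for the shipped experiments: transform-recovery runs at the
native 0.30 mm voxel spacing with generator pitch 0.5 mm; the 20-ramus
cohort runs at 0.6 mm spacing with generated meshes as the analysis surfaces;
the resorption-recovery study runs the full chain (segmentation,
reconstruction, decimation) at 0.4 mm on three rami.  These sizes are the
package's validation conditions; every tolerance asserted by the acceptance
suite is independent of them.

## What the phantoms do and do not show

The phantom reproduces the geometric and statistical structure of the
assessment problem: extremal-landmark definitions, a two-component superior
anatomy separated by a saddle, threshold-separable bone, known rigid truth,
localized monotone volume loss, and observer noise in both landmark picks
and ROI painting.  It does not emulate CBCT physics (scatter, beam
hardening, metal artefacts), real segmentation ambiguity at the
temporomandibular joint space, osteotomy hardware, or true biological
remodelling patterns.  Passing tests therefore demonstrate correctness of
the measurement machinery and the claimed mechanisms (stable-reference
registration isolates condylar change; an uninformative ROI is detected, not
silently misregistered; interobserver error grows away from the reference
structure), not clinical accuracy on patient data.

## Known limitations

* The voxel engine's recovered pose on two-level synthetic volumes is
  accurate to ~0.1 voxel but its run-to-run sensitivity to ROI jitter is
  larger than the surface engine's, mirroring the clinical reliability gap;
  its interobserver error gradient is correspondingly noisier, so the
  distance-gradient finding is asserted on the surface method.
* ICP convergence under severe reference remodelling can need more than the
  default 200 iterations (the extreme-case experiment allows 500).
* The decimator's deviation bound is enforced through the midpoint gate and
  verified vertex-to-surface; it is not a certified two-sided Hausdorff
  bound for arbitrarily non-smooth inputs.
* `fill_mask` fills internal cavities only; it does not close surface
  channels connecting a cavity to the outside (the phantom has none).
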