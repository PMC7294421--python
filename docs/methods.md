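# Methods

This note documents the geometric model behind `woundmetrics`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Measurement model

A pressure injury is modeled as a depression in a locally planar patch of
skin. The plane through the wound rim ("boundary hyperplane") is the
reference for everything: depth is measured from it, the closing surface
for the volume lies in it, and the axes are measured in it. The model
assumes:

* the rim vertices lie near a common plane (RANSAC absorbs outliers from
  segmentation spillover and scanner noise);
* the wound floor is below that plane (concave). The volume of a wound
  bulging above its rim — typical over the femur or the heel — is not a
  well-posed quantity for the rim-closure construction: summing tetrahedra
  from the closure centroid then adds sub-volumes that are not wound. Such
  wounds are detected and their volume is withheld rather than reported;
* the mesh is in meters with faces counter-clockwise when seen from
  outside the body. Reports convert to cm/cm²/cm³ only at the end.

Pipeline stages and the quantities they compute are summarized in the
README; the subsections here give the choices inside each stage.

### Rasterizer

A deliberate, dependency-free software rasterizer (the face-index buffer —
which faces lie under which pixel, in depth order — is the load-bearing
artifact; the shaded image is for inspection only).

* Pixel `(i, j)` has its center at `(j + 0.5, i + 0.5)`; a face covers a
  pixel iff the pixel center is inside its projected triangle; ties on
  shared edges are resolved by a top-left fill rule. This makes
  mask ↔ buffer alignment exact and the rasterizer testable against a
  brute-force point-in-triangle oracle (the test suite asserts exact hit-set
  equality on small meshes).
* Depth is camera-space z in meters (perspective-correct, via linear
  interpolation of 1/z), not normalized device depth — downstream geometry
  needs meters.
* `faces_per_pixel = 5` depth layers per pixel by default. One layer loses
  the overhung interior of deep wounds: on a deeper-than-hemisphere test
  wound, interior-face recall is ≈ 0.96 with 5 layers and ≈ 0.40 with 1
  (the regression test keeps this gap).
* Back-facing triangles are rasterized (no culling): the underside of an
  overhanging rim legitimately faces away from the camera.
* The mesh centroid is moved to the world origin before rendering so the
  0.3 m camera distance is measured to the wound, mirroring the hand-held
  acquisition distance.

**Operating regime.** A pixel-center rasterizer records a face only if the
face's projection covers at least one pixel center, so the buffer is
complete only when projected faces span a few pixels. At the default
0.3 m / 60° field of view, one pixel is ≈ 0.7 mm at 512², ≈ 0.17 mm at
2048². Scanner meshes (≈ 1 mm edges) are comfortably resolved at 1024–2048;
for finer meshes, raise `image_size` until faces cover ≳ 4 px². The
measurement-grade configuration used by the validation experiments is
`image_size = 2048` for ~1 mm-edge meshes.

### Camera

Azimuth/elevation/distance place the camera on a sphere around the origin
looking inward (the acquisition pose is azimuth 0, elevation 0, 0.3 m).
The protocol fixes those three numbers but not the field of view or the
image size; both are configuration with defaults 60° and 512 px. The
pixel ↔ meter scale depends on them, so both are echoed into every report.

### Projective mask transfer

* Fitting is the normalized DLT: Hartley-normalize both point sets
  (centroid 0, mean radius √2), solve the 2n×9 system by SVD, denormalize,
  scale so `H[2,2] = 1`. Four points interpolate exactly (≤ 1e-6 px
  residual asserted); more points give the algebraic least-squares fit.
  The independent cross-check in the tests is
  `skimage.transform.ProjectiveTransform`, which agrees to 1e-8 on exact
  data and to < 0.01 px on noisy data (the two differ only in
  normalization convention).
* Warping is inverse mapping with nearest-neighbour sampling: binary masks
  stay binary without re-thresholding, at the cost of a ≤ 1 px rim
  nibble (the round-trip property test bounds it).
* The warped mask is dilated (disk element) before extraction so the whole
  wound margin is retained despite segmentation under-reach. Default
  radius 2 px at the default 512² view. For pixel-exact masks (the
  synthetic scenes) a 1 px guard band is appropriate and is what the
  validation experiments use; dilation directly inflates the measured
  axes by ≈ 2 px · pixel pitch, so it should reflect the real mask
  uncertainty, not more.
* Landmark matching between the photograph and the top view is an input
  (CSV/JSON file). Automatic matching is a separate, image-content problem
  deliberately out of scope.

### Region extraction

All depth layers of the buffer are consulted for both boundary and interior
pixels. A face under both boundary and interior pixels is assigned to the
boundary ("boundary precedence"): the boundary ring feeds the plane fit, and
erring toward more rim support stabilizes RANSAC. Interior faces only enter
the area sum by default (`include_boundary_area` flips this): the boundary
ring is mask-resolution-, not wound-, sized, and the dilation guard band
means boundary faces are predominantly healthy skin.

### Plane fit, alignment and orientation

RANSAC with a 1 mm inlier threshold and 1000 iterations (seeded, fully
deterministic), followed by iterated total-least-squares refits on the
consensus set until it stabilizes. The defaults are configurable; 1 mm
matches structured-light scanner noise. The 70%-inlier robustness test
requires the fitted normal within 0.5° of truth across 20 seeds.

The plane normal is oriented along the *body-outward* direction, taken as
the mean normal of the boundary (skin) faces — not by the side the wound
interior happens to lie on. Orienting by the interior would silently flip
the frame of a convex wound and make every wound look concave, defeating
the validity gate. Synthetic meshes are consistently oriented by
construction; for real meshes of inconsistent orientation, pass an explicit
`orient` direction to `ransac_plane` (e.g. the camera direction).

Depth uses `|z − z₀|` even for vertices above the plane; the concavity gate
(default: invalid when > 5% of interior vertices sit more than the RANSAC
threshold above the plane) decides whether that number is trustworthy.

### Closure, axes, volume

* "Center of the closing surface" = area centroid of the rim hull polygon.
  For the closed surface the tetrahedron sum is origin-invariant, so this
  choice only affects triangle quality, not the volume (asserted to 1e-6).
* Axes are the sides of the *minimum-area oriented* rectangle of the hull
  (rotating calipers over hull edge directions). An axis-aligned box would
  make the axes depend on arbitrary world orientation; a config flag
  restores it for comparison.
* For the volume, the wound triangles (normals up, out of the body) are
  reversed and combined with the upward-facing lid so the closed surface is
  consistently outward-oriented; the reported volume is the absolute value
  of the signed sum.

## Synthetic generator

The generator stands in for patient data: it emulates a roughly planar
skin patch (a disk plate) containing a depression with closed-form truth.

* **Shapes.** `spherical_cap` (R, h; h > R gives an overhanging rim),
  `ellipsoidal_pit` (semi-axes; surface area by Gauss–Legendre quadrature,
  the one quantity without a closed form), `flat_disk` (zero-depth limit),
  `convex_bump` (mirrored cap; truth marks the volume invalid).
* **Meshing.** Geodesic-style rings: each ring's vertex count is
  proportional to its circumference, giving near-uniform ~`arc/resolution`
  edge lengths (uniform counts would make near-pole faces sub-pixel
  slivers — a meshing artifact no pixel-sampling rasterizer could see, and
  unlike scanner output). Rings of unequal counts are joined by an angular
  merge sweep; the depression rim is a single closed edge loop by
  construction, and interior/boundary labels are exact.
* **Wound margin.** The first plate ring outside the rim (the labeled
  boundary band) has width `edge/5` so the margin converges onto the true
  rim under refinement.
* **Default conditions** (the validation experiments): R = 2 cm, h = 1 cm,
  resolution 30 (≈ 12k faces, ≈ 0.7 mm edges — scanner-like), tilt 25°,
  no vertex noise, plate radius 5 cm. Noise, when enabled, is applied
  along vertex normals so the rim stays near-planar.
* **Scenes.** The true top-view mask marks pixels whose buffer layers hold
  a labeled wound face; the "photograph" mask is that mask pushed through a
  bounded random homography (jittered image corners), and ≥ 8 exact
  correspondences are emitted together with the true matrix for oracle
  checks.

What the generator does **not** emulate: scanner noise spectra and holes,
skin texture and color (there is no photometry anywhere in the pipeline),
segmentation errors beyond the geometric mask transfer, and landmark
mismatches. Passing tests therefore demonstrate the geometric correctness
of the pipeline under controlled conditions, not robustness to real
segmentation or matching failures.

## Validation and tolerances

* End-to-end on the default cap scene: every measurement within 5% of its
  closed form (measured: depth ≈ 0%, area ≈ 0.8%, volume ≈ 0.4%, axes
  ≈ 2%); with exact region labels (isolating the measurement block) within
  2%; errors non-increasing over three refinement levels.
* Rasterizer: exact hit-set equality with the brute-force oracle on
  ≤ 200-face meshes; homography recovery to 1e-6 over 1000 random
  instances; volume against an independent voxel-column integration within
  1%; scale equivariance (s, s², s³) to 1e-6.
* Axes carry the largest end-to-end error (≈ 2%): the mask-boundary ring
  sits up to dilation + 1 px outside the true rim, and the hull inherits
  that bias. It shrinks linearly with pixel pitch.

## Known limitations

* Measurements quantify only faces recoverable through the top view; a
  wound cavity hidden behind a fold (not merely overhung) is unmeasurable
  from a single viewpoint.
* The rim-plane model degrades on strongly curved body sites where the
  healthy skin around the wound is itself far from planar.
* Area is true 3D surface area of the scanned wound bed; on very noisy
  meshes surface roughness inflates it.
* `faces_per_pixel = 5` suffices for single overhangs; pathological
  many-fold surfaces would need more layers.
* MAE/RMSE helpers assert `RMSE ≥ MAE` (a mathematical identity for any
  sample); published wound-measurement error tables occasionally violate
  it, which indicates an inconsistency in those tables, not a property to
  reproduce.
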