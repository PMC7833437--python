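# Methods

`plantcloud` reconstructs clean 3D models of potted plants from
time-of-flight (TOF) depth-camera captures on a turntable rig. This note
documents the models and procedures the package implements, the parameters
that matter, what the synthetic generator does and does not emulate, and
the design choices made where the published pipeline left the design open.

## The problem

A TOF camera (e.g. a 512×424 depth sensor ~0.75 m from the plant, tilted
~30° downward) delivers single-frame point clouds contaminated by three
noise classes:

* **background noise (BN)** — pot, turntable, wall, everything that is not
  the plant;
* **outlier noise (ON)** — scattered sensor artifacts around the target;
* **flying-pixel noise (FPN)** — spurious returns at depth discontinuities
  whose depth is an interpolation between foreground and background.

Multi-view fusion adds a fourth defect: **layered points** — offset
duplicate copies of the same leaf surface produced by residual sensor bias
and registration error.

The pipeline has three stages: single-frame noise removal; mesh-free
bilateral smoothing; and multi-frame registration with a neighboring-mesh
optimization that collapses layered points.

## Stage 1 — noise removal

Everything operates in the camera coordinate frame (x right, y up, z along
the optical axis; metres).

1. **Acquisition pre-crop** (optional): a coarse axis-aligned crop
   representing the sensor's working depth window, so the far background
   does not dominate the bounding box of step 3.
2. **Boundary precheck**: the six per-axis extreme points are tested with
   the radius-density rule below and removed iteratively until all six
   pass — gross outliers would otherwise inflate the bounding box.
3. **MOBB pose rectification**: the minimum oriented bounding box (MOBB)
   of the cloud is computed (PCA-aligned box, refined by a coarse 5°
   per-axis sweep and coordinate descent over the three Euler angles with
   step 0.5° shrinking to 0.01°, evaluated on convex-hull vertices). The
   rotation mapping the box axes onto the camera axes — the minimum-angle
   assignment among the 24 proper signed permutations — is applied about
   the box center. The camera viewpoint is carried through the same
   rotation so view-ray geometry is preserved for the later angle test.
   In the planar ideal construction the rotation angle equals the camera
   tilt.
4. **Pass-through crop**: axis-aligned intervals in the rectified frame.
   Rectification is what makes a tight crop safe when the plant's axis is
   not perpendicular to the camera projection.
5. **Radius-density outlier filter**: for each point, K = number of
   neighbors within radius r (self excluded) and d̄ = mean distance to
   those neighbors. A point is removed iff K < k_min or
   d̄ > μ + n·σ, where μ, σ are the mean and standard deviation of d̄
   over the whole frame. The alternative literal conjunction
   (d̄ > μ + n·σ **and** K > k_min) is available as
   `strict_paper_inequality`; it removes only dense clusters with large
   spread, which contradicts the sparsity intuition of an outlier filter,
   so the disjunction is the default.
6. **Normal estimation**: per-point PCA over the k = 30 nearest neighbors;
   the normal is the smallest-eigenvalue eigenvector, oriented toward the
   viewpoint. Degenerate (zero-covariance) neighborhoods yield NaN
   normals, which downstream stages treat as "cannot judge".
7. **Flying-pixel removal**: flying pixels lie strung along view rays, so
   their (estimated) normals are nearly perpendicular to the viewing
   direction. A point is removed when the angle between its normal and
   its view ray, folded to [0°, 90°], exceeds θ_angle (default 85°),
   i.e. |cos θ| < cos θ_angle. By default both vectors are first
   projected onto the camera xoz plane (robust for the vertical silhouette
   edges a plant presents); a `full_3d` mode skips the projection.

**Parameter matching.** The density-sensitive parameters must be matched
to the point spacing, which is set by the pixel footprint
(2·D·tan(FOV/2)/W ≈ 2 mm at D = 0.75 m for a 512-pixel, 70° sensor). The
package defaults follow the published working values for that density
(r = 2 mm, n = 2, θ_angle = 85°); the Eq-style density floor k is not
published and defaults to a conservative k_min = 2. The synthetic-scene
configurations use r = 3.5 × footprint and k_min = 4, derived from the
same footprint calculation at the render resolutions used.

`calibrate_denoise_config` builds a full configuration from one noiseless
reference capture: the pass-through intervals are the rectified-frame
bounding box of the reference frame's plant points plus a 15 mm margin
(3 mm on the face toward the pot, where the stem base sits exactly at the
pot plane — crop thresholds are naturally asymmetric on the vertical
axis). This is the synthetic analogue of choosing thresholds that
"preserve a complete plant" against a manually segmented benchmark frame.

**Evaluation.** VPP (valid-point percent) = 100 × plant-labeled points /
total points of the filtered cloud; NRR (noise-reduction ratio) =
100 × (1 − n_after/n_before). Both are exact here because every synthetic
point carries a ground-truth label.

A caveat worth stating: d̄ > μ + n·σ is a *relative* criterion — it
removes the tail of the d̄ distribution on any input, including perfectly
clean frames, where the tail comes from the obliquity-stretched pixel
footprint (~4–5% at n = 2). The clean-data retention test therefore
neutralizes the statistical trim and verifies only that the geometric
stages (crop, rectification, angle test) preserve clean data.

## Stage 2 — bilateral smoothing

Continuous-wave TOF sensors exhibit a periodic depth bias ("wiggling")
plus axial noise. The mesh-free bilateral filter moves each point only
along its own normal by the weighted mean of its neighbors' normal
offsets h_j = ⟨n_i, p_j − p_i⟩:

    α_i = Σ_j Wc(‖p_j − p_i‖) · Ws(h_j) · h_j / Σ_j Wc · Ws,
    p_i′ = p_i + α_i n_i,

with Gaussian kernels Wc(x) = exp(−x²/2σc²) (spatial) and
Ws(x) = exp(−x²/2σs²) (range, on the signed normal offset). α is a convex
combination of the h_j, so |α| never exceeds the largest neighbor offset.
Updates are simultaneous (Jacobi) within a pass — deterministic and
order-independent.

Defaults σc = 10 mm, σs = 0.1 mm follow the published working values read
in millimetres. σs is the feature scale: offsets ≫ σs (edges, the gap to
a neighboring leaf) receive vanishing range weight and are preserved.
Note that σs must sit *above* the noise amplitude to smooth it — the
synthetic suites use σs = 2 mm against 0.5 mm noise with a 20 mm step
edge, giving ≥50% RMS reduction at <0.1% edge erosion. As σs → ∞ the
filter tends to the plain Gaussian-weighted mean; as σs → 0 displacements
collapse toward zero.

## Stage 3 — registration and layered-point elimination

Frames are folded left-to-right. Per new frame:

1. **Registration**: rough alignment from the turntable prior (the known
   rotation increment about the turntable axis; a feature-based global
   registration backend can be plugged in instead), refined by
   point-to-point ICP (nearest-neighbor correspondences gated at
   5 × voxel, closed-form SVD alignment per iteration, stop when the RMSE
   improvement < 1e-7 m). The global transform chain M_glo accumulates
   the per-pair steps; `est_transforms[i]` maps frame i into frame 0's
   coordinates.
2. **Meshing**: local-projection triangulation — each point's radius
   neighborhood is projected onto the point's tangent plane and
   Delaunay-triangulated in 2D; triangles incident to the point are
   collected over all points and deduplicated. Triangles are rejected
   when an edge exceeds max_edge (default 5 mm) or μ = 2.5 × the local
   nearest-neighbor distance, or when degenerate (relative flatness
   < 1e-4). A deterministic sub-nanometre jitter keyed to the input order
   breaks cocircular ties consistently, so regular grids triangulate
   without duplicate or crossing patches.
3. **Patch-pair classification**: for each patch of the accumulated mesh,
   the ≤ 3 nearest new-frame patches by centroid. A pair is **parallel**
   when sin(inter-plane angle) < parallel_eps; otherwise the two planes
   meet in a line L and the pair is **intersecting** when the segments
   L∩A and L∩B overlap (Möller-style interval test), **plane
   intersecting** when L crosses the interior of exactly one triangle,
   and disjoint otherwise (disjoint pairs are left alone).
4. **Median-plane projection**: the median plane of a pair is the
   normal-bisector plane through the midpoint of the two centroids
   (normals oriented to a common hemisphere first). Intersecting /
   plane-intersecting pairs with angle > α_min (20°) have the new-frame
   patch projected onto the median plane — halving the pair angle per
   sweep; plane-intersecting projections are cancelled when any vertex
   displacement d_pro exceeds d_pro_max (10 mm). Parallel pairs have
   *both* patches projected; the projection is cancelled when the
   projected patches end up more than d_cen_max (10 mm) apart or when it
   would drag a patch centroid farther than d_cen_max (patches that far
   apart are different surfaces, not layers). Vertices shared by several
   patches move to the mean of their proposed positions. Sweeps repeat
   until no projection fires; a projected pair is completed once its
   angle falls below α_min or its projection distances fall below
   d_min = 2 × the pair's centroid distance.
5. **Merge + down-sampling**: the two clouds (surface-supported mesh
   vertices) are concatenated and voxel-grid down-sampled (one centroid
   per occupied 2 mm voxel; labels reduced by majority).

**Layering metrics.** AveEd = mean plane-to-plane (centroid-to-plane)
distance over parallel pairs; AveAn = mean inter-plane angle (degrees,
folded to [0°, 90°]) over intersecting + plane-intersecting pairs, both
over the same neighbor retrieval as the optimizer. Plane-to-plane
distance (rather than centroid-to-centroid) makes AveEd exactly zero for
a mesh paired with itself, which a lateral-neighbor retrieval would
otherwise prevent.

**Numerical conventions.** The parallel test's published tolerance
(sin α < 1e-6) is kept as the default, but discrete meshes estimated from
noisy points are never parallel at that tolerance; practical
configurations use an angular tolerance at the mesh's normal-jitter scale
(the suites use sin 5°). The AveAn sweep trace decreases strictly until a
convergence plateau where the population-based mean can oscillate by a
fraction of a degree (pairs re-enter the intersecting class as vertices
move); the monotonicity check allows that plateau noise. The per-pair
stop distance d_min = 2 × centroid distance is almost always satisfied
after one projection — the sweep count is governed by newly triggered
pairs, not by re-processing.

## Synthetic scenes

The generator emulates the study rig: a parametric plant (stem + curved
leaves tessellated from bicubic-arc profiles; default a 10-leaf rosette
with 0.17 × 0.10 m leaves — broad enough to shade its pot, as a real
rosette does) on a pot and turntable, a background wall, imaged by a
pinhole depth camera (512×424, 70°×60° FOV, 0.75 m, 30° tilt) via
perspective z-buffer rasterization (exact planar depths at pixel-center
rays). Sensor noise:

* axial Gaussian noise along each ray (default σ = 1.5 mm, typical for
  TOF at 0.75 m);
* sinusoidal wiggling bias, amplitude 1 mm, frequency 20 m⁻¹ of range;
* flying pixels: rays adjacent to depth jumps > 5 cm re-emit, with
  probability p, at a uniform depth between the two sides (label FPN);
* outliers: a fraction of extra points uniform in a shell around the
  plant (label ON).

All randomness flows from one integer seed through seed-sequence
splitting, so stages re-run independently and deterministically. Every
point carries exactly one ground-truth label, replacing manual
segmentation in the metrics.

What the generator does **not** emulate: radiometric effects (IR
intensity, multipath, lens distortion), correlated speckle, and botanical
detail beyond curved, mutually occluding leaves. Passing suites therefore
demonstrate correct behavior of each algorithm against its own noise
taxonomy — not sensor-calibrated performance on real captures. The
uniform flying-pixel depth model is the simplest consistent with
boundary-interpolation artifacts; its consequence (curtain points within
~4 cm of a surface acquire surface-like normals) is why the two-plane
suite measures FPN removal with the stages in pipeline order
(density filter first, then angle test).

### Fixtures and problem sizes

Chosen once, as the package's study conditions:

* **Standard denoise frame**: full scene (wall, pot, turntable) at
  320×264 rays, generator noise defaults; config from
  `calibrate_denoise_config` on a noiseless reference.
* **Two-plane FPN scene**: foreground plane at 0.75 m covering the left
  half of the view (spanning the full vertical FOV so the only depth
  edges are vertical silhouettes), background at 1.2 m; 512×424 rays,
  p = 1.
* **Layered-leaf ratio fixture**: two independently sampled layers of
  one leaf surface at ±1.5 mm along the surface normal, vertex noise
  σ = 0.2 mm (a post-smoothing residual), n = 1200 per layer, meshed at
  max_edge = 10 mm.
* **Collapse fixture**: offset-copy layers of the same sampling (the
  clean layered situation of a doubled leaf); collapse is measured by the
  99th-percentile point-to-surface distance and by the normal-offset
  spread of a central cross-section band (two layers ≈ 3.5 mm spread →
  single layer < 1 mm). A handful of isolated vertices (faces entirely
  inside the 5°–20° band that is below the projection trigger but above
  the parallel tolerance) do not move, so the strict maximum distance is
  not a meaningful collapse statistic for this method.
* **Turntable sequence**: plant-only scene, 8 frames at 45°, axial
  σ = 1 mm, 280×232 rays, per-frame bilateral smoothing (2 passes,
  σs = 2 mm), voxel 2 mm. Ground truth for the chamfer is the noise-free
  visible-surface sampling over the same sweep (occluded regions are not
  part of the reference).

## Known limitations

* The MOBB search is a local refinement with a coarse global sweep; it is
  within 5% of a 1°-grid exhaustive search on rotated-box fixtures but
  carries no global optimality guarantee (exact rotating-calipers search
  is out of scope).
* Pose rectification only helps when the object's bounding box is
  anisotropic; for a near-isotropic rosette plus turntable the box
  orientation is weakly determined and rectification is a no-op (the
  suites assert the ordering benefit on an elongated tilted-pose plant).
* The xoz-projected flying-pixel test is blind to horizontal depth edges
  by construction; the full-3D mode covers them at the cost of normal
  sign sensitivity near grazing surfaces.
* Disjoint patch pairs and pairs in the angular band between the parallel
  tolerance and α_min are never adjusted — layered regions whose meshes
  disagree by 5°–20° survive the optimizer; in the pipeline they are
  averaged away only by voxel merging.
* Point-to-point ICP with a turntable prior has no global rescue: a wrong
  prior (e.g. wrong rotation direction) is not recovered.
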