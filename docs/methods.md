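# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `phyto3d`. It states nothing the test suite or
`scripts/acceptance.py` do not themselves compute.

## The measurement problem

A phenotyping study compares two ways of acquiring a plant's 3D shape: a
close-up triangulation laser scanner (dense, metric, micrometre-level
accuracy — the reference) and photogrammetric reconstruction from hand-held
camera images (sparse, arbitrarily scaled, with characteristic false points
at leaf/stem borders — the test method). Four organ-level parameters are
extracted from each cloud — single leaf areas, cumulated leaf area,
main-stem height, convex-hull volume — and the methods are compared by
linear regression (R²), RMSE and MAPE, with the laser values as the
reference (`ref`) series.

No public clouds exist for such a study, so the package includes a
generator of tomato-like plants whose phenotype is known analytically.
Every pipeline stage is therefore testable against ground truth — including
a truth-referenced benchmark of *both* sensors, something a real study
cannot do.

## Synthetic plant model

**Architecture.** A main stem rises from the substrate plane (z = 0) to
1.4× the cotyledon-node height, with a sinusoidal lateral bow
(`stem_curvature`, default 3 mm). Lateral branches leave the stem at and
above the node (the first one exactly at it, defining the node
geometrically); each non-cotyledon leaf sits at a branch tip. The two
cotyledon leaves attach directly to the stem below the node. Ground-truth
main-stem height is the base-to-node distance.

**Leaves.** The outline is the cordate polar curve
`r(θ) = a (1 + cos θ)(1 + ε sin kθ)` with small serration ε ∈ [0.03, 0.08]
and k ∈ [5, 9]. Two deformations embed the flat region in 3D:

* *Bend* — an isometric circular-arc wrap of the midrib
  (`leaf_bend` ∈ [0, 1] sets the arc angle, up to ~86°). Being an isometry
  it leaves the area unchanged, which gives an exact oracle for the area
  quadrature.
* *Crookedness* — a low-frequency sinusoidal displacement along the local
  surface normal (amplitude `leaf_crookedness`, ~1 wave per leaf span). The
  wave slope is capped at ~0.4 so the surface stays sheet-like: stronger
  waviness would curl the leaf beyond what the projection-based meshing
  (and a real measurable tomato leaf) supports.

**Ground truth.** Leaf areas are computed by triangulated quadrature of the
embedded parameterization on an n×n polar grid (default n = 256,
discretization error O(n⁻²); doubling n changes results by ≪ 0.05 %, which
a test asserts). Hull volume comes from the convex hull of a dense
noise-free surface sampling; at the 0.25 mm pitch used in experiments the
volume differs from a 0.1 mm sampling by < 10⁻⁵ relative (the hull sees
only extreme points), while costing 10× less. The exact reduction
`hull(S) = hull(∪ hull-vertices(chunks))` keeps qhull fast on multi-million
point sets.

**Growth.** A day series reuses the same per-leaf random streams, so the
*same plant individual* grows: stem height and leaf sizes scale by
`growth_rate^day` (default 1.15 → ~120 mm height gain over 6 days, matching
a young tomato's monitoring window), and 1–2 new leaves appear per day.
Defaults give day-0 cumulated leaf areas of ~8·10³ mm² growing to
~4–5·10⁴ mm².

## Sensor models

Both sensors sample organ surfaces on jittered grids at a target
point-to-point spacing; leaf outline rings are sampled at *half* that
spacing (borders are high-gradient regions that multi-view matching
reconstructs densely, and a laser line scan does not thin at a physical
edge). Colors are textured plant greens in HSV (saturation ≥ 0.45), so the
color filter has a well-separated target.

* **Laser** (reference): 0.5 mm spacing, i.i.d. Gaussian noise with
  σ = 45 µm (the stated accuracy of such scanners), metric units, no
  artifacts. The real instrument delivers millions of points; sampling at
  the later 0.5 mm rasterization pitch is a deliberate scaled-down problem
  size (see *Limitations*).
* **Photogrammetric** (test): point budget interpolated 15k → 55k across
  the series (scene-scale reconstruction counts), global scale drawn
  log-uniformly per cloud (the reconstruction is arbitrarily scaled), and a
  rectangular 600 × 400 mm table frame below the plant whose long edge is
  the known reference length for rescaling. Reconstruction error is modeled
  as a smooth Gaussian random field (random-Fourier-feature RBF, pointwise
  σ = 0.5 mm, correlation length 12 mm) plus residual per-point jitter
  (σ = 0.05 mm): MVS error is dominated by smooth, regularized deviations,
  but no reconstruction — even after smoothing — is jitter-free. The jitter
  amplitude was calibrated so the study reproduces the few-percent
  leaf-area disagreement such comparisons report; a purely smooth field
  would make the sparse method *more* accurate than the reference, and
  i.i.d. noise at 0.5 mm would triple-digit-inflate triangulated areas.
  False points are modeled as small white/grey clusters (3–7 points,
  ~0.6 mm spread) spawned with probability `artifact_rate` per leaf-border
  point and offset ~1 mm along the surface normal — dense grey mats at
  borders, the signature false-match pattern against a bright background.
  Isolated single false points would be caught by the geometric outlier
  filter alone, leaving color filtering nothing to do, which is not what
  border artifacts look like in practice. Small leaves additionally lose a
  border-first fraction of points (`occlusion_rate`, default 2 %),
  emulating the filigree-structure losses of sparse reconstruction.

Sampled clouds carry true organ labels and an artifact flag. These are
evaluation channels: the measurement chain reads them only in the explicit
label (oracle) segmentation/crop modes.

## Preparation chain

Order: metric scaling → crop → outlier removal → color filter → (laser
only) rasterization.

* **Scaling** multiplies all coordinates by `true_length_mm /
  measured_length` about the origin; for synthetic clouds the measured
  length is the distance between the embedded frame's corner markers.
* **Crop** removes points below the base plane (table, substrate) or, in
  oracle mode, keeps exactly plant-labeled points.
* **Outlier filter**: a point is removed when its mean distance to k = 16
  nearest neighbors exceeds the global mean + 2.5 σ of that statistic. The
  threshold carries a 10⁻¹² relative epsilon so perfectly regular
  (zero-variance) point sets are never split by floating-point jitter.
  One pass only: re-applying the filter recomputes the threshold on the
  cleaned distribution and can remove further points, so idempotence holds
  for the color and crop filters but is not claimed here.
* **Color filter** removes points with HSV saturation ≤ 0.15 and
  value ≥ 0.5 — pure white and mid-grey fall inside this region, saturated
  greens far outside. Dark greys (shadow) are deliberately kept.
* **Rasterization** partitions space into cubic cells (edge 0.5 mm,
  anchored at the cloud's minimum corner) and keeps one representative per
  occupied cell: member centroid, majority label and artifact flag, and
  per-channel mean color (a "majority" over 24-bit colors is ill-defined;
  the mean is the stable choice). Re-rasterizing re-anchors the grid and
  may merge adjacent representatives, so this stage is a
  partition-representative map, not an idempotent filter.

On artifact-bearing photogrammetric clouds the default chain removes
> 95 % of flagged false points while losing < 1 % of true plant points
(property-tested over five seeds).

## Parameter extraction

* **Segmentation**: label mode passes ground-truth organ classes through
  (the automated stand-in for manual organ cutting). Geometric mode
  computes covariance eigenvalue features in a 6 mm neighborhood
  (neighbor lists radius-bounded, stride-subsampled to 64 for the
  covariance): elongated neighborhoods (linearity > planarity) are
  stem/branch, sheet-like ones leaf. A sheet *border* also looks linear, so
  linear points additionally require a genuinely three-dimensional
  neighborhood (λ₃ ≥ 0.25 λ₂ — true for a tube's ring, ~0 for any flat
  region). Single leaves are connected components of the leaf class at a
  2.5 mm gap threshold.
* **Cylinder fit**: 5 parameters (axis point constrained to the plane
  through the centroid, direction, radius), orthogonal residuals,
  initialized from the principal covariance axis, refined by
  Levenberg–Marquardt to 10⁻¹² tolerances. Height is the extent of point
  projections on the fitted axis, since the least-squares cylinder itself
  is unbounded. Noise-free cylinders are recovered to machine precision;
  degenerate (collinear, < 10 points) inputs raise.
* **Stem selection**: all stem-class points between the base (lowest axial
  position) and the cotyledon node. The node is detected from the lowest
  branch junction: branch points pressed against the stem (within 0.5 stem
  radii of stem points) trace the attachment ring, and the 15th percentile
  of their axial positions estimates the node with ≲ 1 mm bias (the cluster
  mean overshoots upward along the branch; the minimum undershoots by about
  a branch radius). All selection happens in projections on the stem's own
  fitted axis, making the measurement rigid-motion invariant.
* **Leaf meshing**: principal-plane projection, 2D Delaunay, pruning of
  triangles whose longest edge exceeds 3× the median nearest-neighbor
  spacing, area as the 3D triangle-area sum. Strongly folded point sets
  (normal-direction spread beyond 0.3× the in-plane spread) trigger a
  warning, as plane projection stops being injective. Analytic squares,
  discs and isometrically bent rectangles are recovered within 1 %.
* **Hull volume**: qhull on the full prepared plant cloud, mm³ → dm³.

## Study design and evaluation

The default experiment is 5 plants × 6 days × both sensors (30 clouds per
method). Laser values are always `ref`, photogrammetric values `act`; 26
single leaves are drawn from the first two plants, stratified by reference
area into small/medium/large terciles. All randomness derives from a master
seed through `SeedSequence` spawn keys (per plant, per day, per sensor), so
any subset reruns identically and repeated runs are byte-identical.

The cleaning-influence table measures the first plant's final-day clouds
with and without the cleaning stages (outlier + color removal), keeping
scaling/cropping/rasterization in both variants so the difference isolates
cleaning itself.

Because truth is known, the report also benchmarks each method against
truth. Aggregated over seeds, the laser chain is closer to truth for the
surface-sensitive parameters (cumulated leaf area ~1.4 % vs ~2.2 % MAPE;
hull volume ~0.1 % vs ~0.6 %). Main-stem height is limited by the shared
junction-detection rule (~0.5 % for both methods); the difference between
sensors there is below estimator noise — consistent with stem endpoints
being the ill-defined part of this measurement in practice.

## Numerical choices

* Leaf-area quadrature n = 256 (relative error ~2·10⁻⁴; oracle tests use
  n = 512–1024).
* Truth-hull sampling 0.25 mm in experiments (0.1 mm default in
  `true_parameters`); the difference is < 10⁻⁵ relative and test-asserted.
* Cylinder LM tolerances 10⁻¹², ≤ 2000 function evaluations; fit failure
  with a residual report on non-convergence.
* Rasterization cell keys are flattened integers; ties in majority votes
  resolve to the smaller label.
* Metrics carry full precision; rounding (e.g. one decimal for cleaning
  differences) happens only at the reporting layer.
* PLY ASCII stores float64, binary float32; tests assert bit-exactness on
  the ASCII path.

## Limitations

* The laser emulation samples at the 0.5 mm rasterization pitch rather than
  the instrument's true density (millions of points). Consequently the
  rasterizer cannot average per-point noise the way it would on real data,
  and the laser's meshed leaf area carries a ~1 % noise-roughness
  inflation. This is a scaled-down problem size, not a property of the
  instrument.
* Meshed area is generally noise-inflated: triangulating a noisy surface
  without smoothing biases area upward by roughly ½·E[tan²(tilt)]. The
  chain deliberately contains no smoothing filters, so this bias is part of
  what the agreement analysis measures.
* The synthetic plants are built from smooth parametric primitives: no
  self-occlusion from the camera's viewpoint, no petiole/leaflet
  substructure, no texture-dependent reconstruction quality. Passing tests
  show the measurement chain is correct and the sensor contrasts are
  directionally right; they do not certify error magnitudes on real
  plants.
* Geometric segmentation is a simple eigenvalue classifier, adequate for
  clean synthetic organs; it is the stand-in mode, not the default for the
  study (which uses label mode, as the original manual workflow effectively
  did).
* Scale recovery uses the embedded reference frame's corner markers; real
  studies measure the table edge manually, adding an operator error not
  modeled here beyond sensor noise on the markers.
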