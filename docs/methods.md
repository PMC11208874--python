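# Methods

This note documents the models, parameter choices and numerical decisions
behind `grapecluster`, and what the synthetic-data results do and do not
say about real cluster images.

## Mask records and geometry conventions

Masks arrive in the uncompressed COCO RLE dialect: run lengths in
column-major scan order, first run counting background. The compressed
6-bit string dialect is accepted on read and canonicalized on write.
Coordinates are 0-based pixels, origin top-left, y increasing downward;
the peduncle ("top" of the cluster) is minimal y. Contours are traced on
pixel boundaries (crack edges) with a right-turn rule at pinch vertices,
so the shoelace area of a traced contour equals the pixel count of a
hole-free 4-connected component exactly; for masks with several
components the largest is kept and the rest logged.

Crack-edge contours have staircase perimeters (≈27% longer than the
underlying smooth outline for a disk), so every perimeter-sensitive
metric is computed on a resampled, circularly Gaussian-smoothed contour
(160 arc-length samples, σ = 2 samples). On a rasterized disk of radius
20 px this recovers the perimeter to 0.2%, circularity to 0.003 and the
Feret diameter to 0.8%; areas always use the exact pixel count.

Berry length is the maximum Feret diameter, width the extent
perpendicular to the Feret axis, and aspect = width/length ∈ (0, 1], so
elongation decreases aspect monotonically. Elliptic Fourier descriptors
follow the Kuhl–Giardina chord-length formulation; translation is always
removed, scale optionally (dividing by the first-harmonic semi-major
axis, a rotation-invariant size), rotation optionally (first-harmonic
phase and orientation standardization).

## Filtering

Stage order is overlap → geometric → EFD+PCA, with every removal logged
so the report partitions the input exactly.

*Overlap.* A mask is removed as a multi-berry mask when at least
`min_children` (2) smaller masks are each contained in it with
containment ≥ 0.8. Containment — intersection over the smaller mask —
rather than plain IoU drives this rule because a parent covering two
berries has low IoU with each child but near-total containment of both,
regardless of the parent's size.

*Geometric.* Area bounds (0.2–5× median), minimum aspect (0.4) and
maximum perimeter/area (3× median) are relative to per-image medians,
which berries dominate, making the filter scale-free; absolute fallback
bounds cover scenes with fewer than three masks. The off-cluster test
runs second, on the size/shape survivors only, so the reference circle or
clamp cannot drag the cluster-centre estimate: a record is off-cluster
when its centroid deviates from the survivor median by more than 2 robust
standard deviations (1.4826 × MAD, per axis). Per-axis deviation rather
than radial distance respects the elongated geometry of hanging clusters.

*EFD+PCA.* Up to 5 rounds; each round recomputes EFD harmonics
(translation, scale and rotation normalized) on the survivors, runs PCA
on the flattened coefficients, and removes outlines whose Euclidean
distance from the centroid in the space of the first 10 components
exceeds 2 × the RMS spread of that score cloud (√Σ component variances).
Rounds stop early when nothing is removed; a zero-variance cloud removes
nothing. Two design points deserve explanation. First, rotation is
normalized here (unlike in the exported berry features) because outline
orientation carries no berry/non-berry information, and retaining it
makes the orientation ring dominate the score variance and hide true
outliers. Second, the threshold is on the distance in the 10-component
space with a single cloud-level SD, not ±2 per-component SDs: per-component
sample SDs are self-normalizing, so for any continuous shape
distribution roughly 5% of outlines sit beyond 2 SDs of *some* component
each round, and five recomputed rounds would discard 30–70% of true
berries. The cloud-level rule keeps bounded berry-shape variation intact
(berries are a tight cloud, so no berry is ever 2 cloud-SDs out) while
rachis bits and star-shaped outlines sit far outside and are removed in
the first round or two. On the reference configuration (100 noisy
ellipses + 5 star outlines) it removes 5/5 stars and 0/100 ellipses.

*Scale.* The reference circle is sought among geometric removals as the
most circular object with isoperimetric ratio ≥ 0.9; scale = known
diameter / Feret diameter. A rasterized 140 px circle at 35 mm recovers
0.25 mm/px to better than 0.1%. Without a candidate the analysis
proceeds in pixels with a warning.

## Cluster architecture

Berry "location" is the mask centroid (robust to partial-occlusion
crescents). ECDF profiles shift positions to start at 0, scale the
maximum to 100, and sample the ECDF at 100 coordinates; the recorded
quantiles are the cumulative fractions at coordinates exactly 25/50/75.
Symmetry classes use fixed thresholds: skew_left when q25 > 0.3 and
q75 > 0.8; skew_right when q25 < 0.2 and q75 < 0.7; symmetric when
q25 ∈ [0.2, 0.3], q50 ∈ [0.45, 0.55], q75 ∈ [0.7, 0.8]; otherwise other.

Concave hulls are computed by the GEOS length-ratio algorithm on the
union of berry-outline vertices. The exposed `concavity` parameter maps
monotonically onto the ratio (`ratio = 1 − 1/concavity`): values near 1
follow wing sinuses and shoulders closely, large values smooth them away,
and the limit is the convex hull. The hull always contains every input
vertex, and hull area is non-decreasing in `concavity`. Hull length is
the vertical (y) extent and width the horizontal extent, because clusters
hang vertically in the imaging rig. Compactness is Σ berry areas / hull
area; with boundary-completed masks of partially hidden berries the sum
counts covered area twice, so values above 1 indicate dense clusters
rather than an error. The cross-cluster shape PCA runs on hull-outline
EFDs with scale normalized but rotation retained (clusters share a
canonical hanging orientation), which makes the first component track
elongation/aspect (|r| > 0.99 on an ellipse sweep).

## Occlusion correction

The visible-to-true count model is ordinary least squares
y = β₀ + β₁x in closed form, with adjusted R² = 1 − (1−R²)(n−1)/(n−2).
For counts, x is the maximum visible count across available view angles;
for maximum berry area, views are pooled. Corrected counts are rounded
half-up and never fall below the visible count when β₁ ≥ 1. K-fold CV
shuffles rows with a seeded generator after putting them in canonical
(x, y) order — making the result invariant to input row order — and
computes one R² on the pooled out-of-fold residuals rather than averaging
per-fold R²s, which is unstable for small folds.

## Repeatability

Cluster replicates are averaged to one value per genotype × block (for
count-like traits the per-cluster value is first maximized over view
angles, since the best view is the least-occluded one; shape traits use
the angle mean). Additive block effects are removed exactly by centering
each block at its mean; genotypic and residual variances then come from
one-way ANOVA mean squares with the unbalanced-design coefficient
n₀ = (N − Σnᵢ²/N)/(k−1), negative estimates truncated at zero.
Repeatability = σ²_g/(σ²_g + σ²_e), clamped to [0, 1]; it is invariant to
affine trait transforms. In the balanced 100 genotype × 3 block design
the estimator is unbiased with sampling SD at the intraclass-correlation
information bound (≈ 0.066 at a true value of 0.3), which sets the
resolution limit of such a trial: about one estimate in eight will miss
a true 0.3 by more than 0.1, and no estimator can do better.

## Synthetic clusters

The generator emulates the study conditions rather than photorealism.
Berries are spheres (radius 14 ± 1.2 px ≈ 6.6 mm at the default
0.47 mm/px, i.e. ≈ 135 mm² projected area) packed around a vertical
rachis at internode steps with radial jitter inside a tapered envelope;
pairwise relaxation enforces centre separation ≥ 0.65 × (rᵢ+rⱼ). Berry
count spans 5–130. By default the rachis length scales with berry count
(≈ 5.5 berries per 16 px internode), so clusters grow longer rather than
deeper and the hidden fraction is size-independent — which is what makes
the count underestimation linear. The radial extent per berry radius was
calibrated once so that a single view hides about half the berries
(measured mean visible fraction 0.50–0.55 across 15–125 berries); it is
not re-tuned per experiment. A wing is a smaller sub-cluster offset
laterally at a given azimuth: at view angles where the azimuth projects
onto the image plane the wing adds visible berries, a quarter turn later
it hides behind the main cluster, so opposing views agree and adjacent
views differ.

Rendering is orthographic with a per-pixel z-buffer: the nearest sphere
owns each pixel, visible masks are pairwise disjoint, and partially
hidden berries have crescent-shaped visible regions. Orthographic
projection preserves areas and is sufficient for occlusion logic;
perspective is out of scope. The segmenter emulation emits a record for
each berry whose visible fraction reaches 0.2 (mask generators drop
low-stability fragmentary proposals), and the record carries the berry's
complete, slightly elliptical projected outline (outline aspect uniform
in [0.86, 1.0], tilt within ±20° of vertical) — boundary-completed masks,
consistent with segmenters overestimating the area of partially hidden
berries — not the crescent. Distractors (clamp above the peduncle,
reference circle in a widened free band, thin rachis rectangles,
irregular background stains) and merged masks (unions of touching
berries' outlines) are injected with ground-truth labels. Rendering is
integer-grid and fully deterministic under a fixed seed.

What the generator does **not** emulate: lighting, texture and color
variation (flat fills only), perspective foreshortening, berry softness
and contact deformation, peduncle/pedicel structures, and segmentation
noise (mask boundaries are exact). Passing the recovery suites therefore
shows the *post-segmentation logic* is correct under realistic geometry
and occlusion; it does not certify performance on real photographs with
imperfect masks.

Trial simulation draws value = μ + gᵢ + bⱼ + eᵢⱼ + wᵢⱼc with independent
normal effects (g genotype, b block, e vine-level residual, w cluster
subsampling); the exact vine-level repeatability
σ²_g/(σ²_g + σ²_e + σ²_w/c) is recorded in the table metadata.

## Problem sizes in the standard runs

The test suite and the acceptance script use 50 artifact-laden scenes for
filtering recovery, 200 clusters (20–100 berries) for the
occlusion-correction fit, 30–50 seeds × 4 angles for the angle-dependence
contrast, and 50–100 replicates of the 100 × 3 trial per simulated truth
for repeatability — sizes at which every recovery statistic is stable to
well within its acceptance margin while a full run stays near half a
minute on one CPU.
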