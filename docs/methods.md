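# Methods

`astrolayer` quantifies laminar heterogeneity of neocortical astrocytes
from five kinds of input: 3D labeled cell volumes, process traces or
substructure masks, serial-section EM segmentations, per-cell nuclear
intensity tables, and a paired gene-expression count matrix.  Every
input can also be generated synthetically with known ground truth, so
each quantifier is testable as a parameter-recovery problem.

## Coordinate frame and cortical geometry

Volumes are indexed `(z, y, x)` = (section, row, column) with physical
voxel sizes in µm; physical coordinates sit at voxel centers (0-based).
The cortex is modelled as a flat slab between two parallel planes — the
corpus callosum (relative depth 0) and the pia (relative depth 1) —
with a fixed unit normal.  All downstream computations consume only a
cell's relative depth and the tangent/normal frame, so slab flatness is
not a restriction for the statistics computed here; it does mean the
generator cannot emulate curvature-induced depth gradients within one
field of view.

Relative depth maps to four bins (the convention used for all per-bin
statistics): bin1 [0.9, 1.0], bin2 [0.65, 0.9), bin3 [0.25, 0.65),
bin4 [0, 0.25).  Interval boundaries belong to the more superficial
bin, and 1.0 belongs to bin1, making the assignment total on [0, 1].

## 3D morphometry

Each distinct non-zero label is one cell (26-connectivity is the
declared object model).  The 24-parameter descriptor set per cell:

* **Volume** = voxel count × voxel volume.  **Surface area** by exposed
  -face counting, faces weighted by their physical areas.  Face counting
  over-reads smooth surfaces by the direction-averaged factor
  `mean(|nx| + |ny| + |nz|) = 3/2`; it is exact for axis-aligned blocks.
  Consequently a digitized ball scores sphericity ≈ 2/3 rather than 1;
  tests treat that constant as a calibrated bias, and all comparisons
  between face-count areas are internally consistent.
* **Compactness** `36π V²/A³` and **sphericity** `π^(1/3)(6V)^(2/3)/A`
  (ball = 1 with exact area).
* **Convex-hull metrics.**  The hull of the voxel centers is itself
  voxelized — hull volume counts voxel centers inside it, hull area is
  the face-count area of that voxelized hull — so object and hull are
  measured with the same discrete estimator.  Convex voxel bodies then
  score solidity = convexity = 1 exactly, hull dominance
  (`V_hull ≥ V`) is exact, and the smooth-surface face bias cancels in
  convexity.  Coplanar objects have no 3D hull and are flagged.
* **Ellipsoid fit** from the second central moments of voxel positions
  (plus the per-voxel uniform self-moment `size²/12`, which regularizes
  one-voxel-thick objects).  Semi-axes are `sqrt(5λ)` — exact for a
  uniform solid ellipsoid.  Elongation = R1/R2, flatness = R2/R3 (both
  ≥ 1).  Orientation angles of the major axis against the XY/XZ/YZ
  coordinate planes are inclinations `arcsin` of the out-of-plane
  component, folded into [0°, 90°].
* **Surface-referenced angles.**  The radial/tangential angle is the
  inclination of the major axis against the surface-tangent plane
  (90° = radial); the relative-XZ / relative-YZ pair re-expresses the
  plane angles in the frame where the cortical normal replaces the
  image y axis.
* **Substructure** (e.g. a microtubule channel): voxels inside the cell
  whose signal exceeds a threshold; its volume, surface area and volume
  fraction enter the descriptor set and feed voxel-mode Sholl profiles.
* **Four supplementary ratios** complete the roster of 24: hull
  -complement volume fraction (1 − V/V_hull), surface-to-volume ratio,
  substructure volume fraction, bounding-box fill.  The roster is
  configurable; bimodality screening downstream makes the exact choice
  of supplementary ratios non-critical.

A cell with more than 25% absent entries (degenerate hull/fit) is
excluded with a log entry, mirroring the exclusion of cells whose
morphology cannot be scored reliably.

2D orientation works analogously on z-projected masks via the
second-moment ellipse, reporting elongation and the angle to a supplied
surface-tangent direction.

## Sholl profiles

Tree mode counts actual transversal intersection points of each trace
segment with the sampling sphere (quadratic solve per segment;
tangencies excluded; a node exactly on a shell is attributed to the
segment ending there).  2D mode first drops the section axis.  Voxel
mode counts 26-connected components of the substructure inside
half-open shells `[r − h/2, r + h/2)`, h defaulting to the smallest
voxel pitch.  The ">30 µm from the nucleus" arborization statistic is a
reporting filter (`ShollProfile.filtered`), not hard-coded behaviour.

## Morphological clustering

Features are z-scored (sample sd, constant features dropped).  The
multimodal index of a feature is

    MMI = (M3² + 1) / (M4 + 3(n − 1)² / ((n − 2)(n − 3)))

with M3 the bias-corrected sample skewness and M4 the bias-corrected
sample excess kurtosis — the bimodality-coefficient convention, whose
finite-sample term is exactly the one above.  Population limits: normal
1/3, uniform 5/9, balanced two-point 1.  Features with MMI > 0.55
(just below the uniform benchmark) are retained for clustering.

Clustering is Ward's minimum-variance method on Euclidean distances
(the Ward.D2 contract, scipy's `linkage(method="ward")`), with
deterministic lowest-index tie-breaking.  The cluster number is chosen
by the elbow of the total within-cluster distance curve — implemented
as within-cluster sum of squared distances to centroids (Ward's natural
objective) — operationalizing "sudden marked flattening" as the K
maximizing the second forward difference W(K−1) − 2W(K) + W(K+1).  A
curve linear in K has no elbow and returns `None`; the curve is always
returned.  This rule presumes roughly equal cluster separations: with
strongly unequal separations the largest curvature sits at the first
split rather than at the true K, which is why the synthetic blob
generator places cluster centers on a regular simplex.

Silhouette widths use the standard a/b contrast with the singleton and
a = b = 0 conventions set to 0; values are verified against
scikit-learn's implementation in the tests.  A 2D t-SNE embedding
(exact gradient — the theta = 0 limit — perplexity 30, fixed seed 510)
is available for visualization only and never feeds cluster
assignment.

Layer enrichment uses a two-sided Fisher exact test on the layer ×
cluster table: full enumeration over all tables with the observed
margins (two-sided p = total probability of tables no more probable
than the observed) when a cheap composition bound keeps the candidate
count under 10⁷, otherwise seeded Monte Carlo (default 10⁶ permutation
draws) with the method tagged in the result.  Monte Carlo p-values are
floored at 1/(n_draws + 1).

## Synapse ensheathment

On each serial section the axon–dendrite apposition is the set of axon
pixels 4-adjacent to dendrite pixels, ordered into a path; its two
endpoints are the edges.  The interface perimeter is approximated as

    P = n_sections × 2Δz + cap₁ + cap₂

with Δz the section interval and each cap the in-plane length of the
interface on its first/last section (a configurable alternative credits
half-lengths).  The astrocytic perimeter A sums Δz for every edge with
an apposed astrocyte profile area strictly above 0.005 µm² within a
100 nm contact neighborhood (the area threshold is the quantification
rule; the neighborhood radius is this package's choice, configurable),
plus each covered cap; cap coverage is evaluated on the adjacent
section beyond the span.  f = A/P ∈ [0, 1] by construction.  Default
calibration follows FIB-SEM acquisition: 3.854 × 4.891 nm pixels,
Δz = 20 nm.  Group contrasts (e.g. bin2 vs bin4 synapses) use Welch's
unequal-variance t-test.

## Marker intensity by depth

Raw nuclear-ROI median intensities are min–max rescaled to 0–100 per
image group (a constant group maps to 50 with a warning).  "Positive"
is not defined by the upstream protocol, so the default calls Otsu's
threshold on the scaled distribution, with a fixed-cutoff override; the
applied threshold is surfaced in every output.  Per-bin positive
fractions are computed per animal; the bin effect is tested by one-way
ANOVA on per-animal fractions with Bonferroni-corrected pairwise Welch
tests.  Perivascular-flagged cells are excluded before any counting.

## Paired expression contrast

RPKM = counts × 10⁹ / (library size × gene length bp), with library
size defaulting to the column sum of the provided matrix.  The headline
fold change is the arithmetic mean over animals of per-animal RPKM
ratios (geometric available); the ratio-of-means estimator is emitted
alongside, since the two differ materially for variable genes and the
per-pair estimator respects the paired design.  Pairs with a zero
denominator contribute no ratio; genes with fewer than two usable pairs
are flagged.  Significance is the two-tailed paired t-test on
per-animal RPKM values, reported raw (an optional Benjamini–Hochberg
column exists but is off by default, matching the raw-p reporting
convention of the tables this mirrors).  Enriched-gene tables split by
direction at p < 0.05 and a fold-change cutoff, sorted by fold change;
a gene can appear in at most one table.

## Synthetic data: what it emulates, what it does not

One global seed expands into independent named streams
(`SeedSequence([seed, crc32(name)])`); identical (parameters, seed)
reproduce outputs bit-for-bit.

* **Astrocyte volumes**: oriented ellipsoidal somata (planted volume,
  axis ratios, orientation against the tangent plane) plus recursive
  cylinder-tree processes, laid out on a jittered lateral grid inside
  per-layer depth bands.  Label collisions raise, never merge.  The
  default layer spec encodes the laminar gradient of interest — small
  flat pial cells, radial large-territory arborized upper-layer cells,
  tangential deep-layer cells — with illustrative means/sds, since no
  distributional parameters beyond figure medians exist to calibrate
  against.  Processes attached to a soma perturb its moment tensor by
  ~10–20°, so the 3°-recovery contract applies to soma-only volumes.
* **Feature tables**: Gaussian mixtures over the 24-name roster.  The
  bimodality benchmark plants two balanced components separated by 8
  within-sd on 5 features (population MMI ≈ 0.81 vs the normal limit
  1/3 elsewhere); the cluster benchmark places K centers on a randomly
  rotated regular simplex at pairwise distance 10 sd.  In the 5-D
  informative space that geometry yields a truth-label silhouette of
  ≈ 0.70 (within-cluster distances scale with √dimensions), which the
  tests freeze as the expected value.
* **Synapse stacks**: one rectangular axon–dendrite interface spanning
  a known section range, astrocyte discs planted at chosen edges/caps
  so the quantifier recovers the target fraction exactly on the
  representable grid (worst-case granularity Δz/P ≈ 0.02); 1-px
  boundary jitter emulates segmentation noise.  No EM texture,
  vasculature or non-astrocyte glia are rendered.
* **Expression**: log-normal counts around planted means with a shared
  within-pair animal effect; planted fold changes on a gene subset;
  uniform 500–5000 bp gene lengths.
* **Intensity records**: per-bin Bernoulli positivity with separate
  normal intensity distributions for positive/negative nuclei.

Passing recovery tests on these generators demonstrates that the
quantifiers are correct implementations of their definitions — not that
real tissue satisfies the generators' assumptions (clean segmentations,
ellipsoidal somata, log-normal counts, well-separated morphotypes).

## Numerical choices and edge cases

* Angles are always folded into [0°, 90°]; degenerate axes (isotropic
  moment ties) yield absent values rather than arbitrary angles.
* Sholl tree mode excludes tangencies (discriminant ≤ 0) and uses
  half-open parameter intervals so shared nodes are never counted
  twice.
* The Monte Carlo Fisher test counts tables with log-probability within
  1e−7 of the observed as "as extreme" to absorb float round-off.
* Silhouette/MMI reject inputs below their minimum n (2 clusters /
  n = 4) explicitly instead of returning NaN.
* Problem sizes in the test-suite and the acceptance script (116-cell
  tables, 50-seed recovery loops, 10-section stacks, 2000-gene null
  matrices) match the study-scale defaults wherever the conditions are
  stated, and otherwise are chosen as the smallest sizes at which the
  statistical contracts are sharp.

## Known limitations

* Face-count surface areas are comparable with each other but not with
  mesh-based areas (×1.5 on smooth surfaces); sphericity and convexity
  inherit the bias (convexity cancels it by construction).
* The elbow rule is a single-number operationalization of a visual
  criterion; for cluster configurations with strongly unequal
  separations it will report the dominant split instead of the finest
  planted K.  The curve is always emitted so the choice can be audited.
* The greedy nearest-neighbor ordering of interface pixels assumes
  simply-curved appositions (true for cross-sectioned synapses); deeply
  folded interfaces would need a graph-based path order.
* Ward linkage can mis-merge a genuine midpoint outlier even at 10-sd
  separation (≈1 cell in 200 runs of the recovery benchmark); mean
  recovery stays ≥ 0.999 ARI.
* No batch/animal random-effect modelling in the clustering module, and
  no multiple-testing correction by default in the expression contrast.
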