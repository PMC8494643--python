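# Methods

`axonmap` quantifies single-neuron morphology and brain-wide axonal
projections from SWC reconstructions registered to a reference atlas.
This note records the models and procedures the package implements, the
parameters that matter, the synthetic data the test-suite runs on, and
the numerical choices made where the design was genuinely open.

## Coordinate conventions

All coordinates are in µm in atlas space, axes ordered
(anterior→posterior, superior→inferior, left→right), origin at the
volume corner. The voxel containing a point is `floor(coord /
resolution)` (0-based); a point exactly on a voxel face belongs to the
higher-index voxel. The left-right axis (index 2 by default) carries the
midline; a point exactly on the midline counts as ipsilateral, which
keeps hemisphere calls deterministic and symmetric under joint mirroring
of point and soma.

## SWC processing

A reconstruction must be a single rooted tree. Validation enumerates
violations rather than raising: duplicate ids, orphan parent pointers,
parent-pointer loops and multiple roots are errors; multifurcations and
child-before-parent row order are warnings, since curated reconstructions
contain both.

* **Pruning** removes terminal branches (tip back to the nearest branch
  point) with path length strictly below a threshold, 10 native units by
  default. Whether the threshold is applied in image pixels or µm depends
  on where in a pipeline the file sits, so the unit is deliberately the
  file's own; the pass is single-shot by default because iterating the
  rule can eat real arbors tip-first (a `cascade` flag enables iteration).
* **Resampling** re-spaces nodes along each unbranched path. Coordinates
  are scaled per-axis by the step (e.g. 64 × 64 × 16 for anisotropic
  image grids), the path is sampled at unit arc-length in that normalized
  space, and branch points and tips are kept exactly; positions and radii
  interpolate linearly. Total cable length converges to the original as
  the step shrinks.
* **Hemisphere flipping** mirrors a neuron about the midline when its
  soma lies right of it, so populations can be compared in a single
  hemisphere. It is an isometry and an involution on right-sided cells.
* **Warping** between atlas spaces applies a smooth thin-plate-spline
  fitted on landmark pairs (scipy's `RBFInterpolator`,
  `thin_plate_spline` kernel, degree-1 polynomial tail). The smoothing
  λ defaults to 0 (exact interpolation); because the polynomial tail is
  affine, any affine relation between landmark sets is reproduced exactly
  (to solver precision) everywhere. At least four non-coplanar,
  duplicate-free landmarks are required.

## Projection quantification

Axon length per brain structure uses a curated set of mutually
non-overlapping mid-ontology structures (configuration, not hard-coded;
the toy atlas ships 8). Each parent-child axon segment is subdivided at
most one voxel long (default substep = smallest voxel dimension), each
piece is credited to the curated roll-up of its midpoint's voxel label
and to the ipsi/contra hemisphere relative to the soma, and lengths are
reported in mm. Cable falling outside every curated structure is tracked
as background, so the per-structure entries plus background always sum
to the neuron's total axon length (machine precision). Midpoint
assignment makes the result insensitive to boundary geometry at the
substep scale and trivially reproducible.

Strengths and target calls follow two fixed transforms: a single-cell
structure is a projection target when it holds **more than 1 mm** of
axon, with strength `ln(length in mm)` above the threshold and 0 below;
a mesoscale (population tracing) structure has strength
`ln(NPV·100 + 1)` and is a target when that exceeds **0.2** (both
thresholds strict). Target counting alternatively uses axon terminals
(tip nodes, a proxy for boutons): a structure with at least one tip
counts, regardless of cable length. Cells and mesoscale experiments are
matched when soma and injection site share a curated structure (and
cortical layer, when both are tagged).

## Arbor detection

A neuron is viewed as a graph whose vertices are reconstruction nodes
and whose edges are parent-child pairs weighted by the similarity
`s = exp(-d/σ)`, with `d` the 3D Euclidean distance and σ a length scale
(default 1 native unit; pass σ near the typical segment length when
using the spectral mode, which otherwise sees weights spread over many
orders of magnitude). For a partition into k connected parts — obtained
by removing k−1 tree edges — the **normalized score** is total
cross-cluster similarity over total within-cluster similarity. For fixed
k the cut minimizing the score is found exactly by enumeration when the
number of (k−1)-edge combinations is small (≤ 2·10⁵ by default) and by
greedy edge removal plus local swap refinement otherwise; a spectral
relaxation on the normalized Laplacian is available when parts need not
be connected.

Choosing k across candidates needs care: for the optimal cut the
normalized score is strictly increasing in k (every extra cut moves
weight from the denominator to the numerator), so "minimize the score
over k = 2..8" degenerates to k = 2 and cannot recover a planted arbor
count. `axonmap` therefore keeps the normalized score as the within-k
cut objective but selects k by **mean silhouette** of the node
coordinates under each candidate partition, the standard model-selection
statistic for spatial cluster counts. A partition whose best silhouette
falls below a floor (default 0.4) — or a neuron smaller than twice the
minimum arbor size (default 10 nodes) — is reported as a single arbor.
On well-separated arbors the silhouette exceeds 0.8 while a split
uniform blob stays below ≈0.2, so the floor is not delicate. The arbor
containing the soma is the soma arbor; local axon is the set of axon
nodes within 200 µm of the soma.

## Cortical geometry

The cortex is cut into consecutive coronal slices (100 µm). Anchor
points are sampled at even arc-length (default 50 µm) along each slice's
outer border; each anchor's inward normal is the in-slice perpendicular
of the local border tangent (±1 neighbours), and its area is its mean
neighbour distance times the slice thickness. Nodes attach to their
nearest anchor; depth is the projection of the offset on the anchor
normal, and the surface position is the node projected back to zero
depth. From these assignments: arbor 2D area (sum of distinct anchors
touched — each counted once), vertical laminar profiles (cable-length
weighted histograms over depth, out-of-range depths clipped into the
edge bins so mass is conserved), tangential span (max pairwise distance
of surface positions), and the apical-dendrite shift (rigid translation
along the local normal placing the shallowest apical node at the top of
L1, configurable as an atlas layer or fixed depth). Arbor radius grows a
sphere around the arbor centre (the node with the smallest mean distance
to the others) until 70% of segments are inside; a segment counts by its
midpoint (a flag switches to full endpoint containment). Normalized
depth divides by the local pia-to-white-matter thickness when available.

## Morphometric features

Global features follow the L-measure dialect: bounding-box
width/height/depth (x/y/z extents), total length, maximum Euclidean and
path distance from the soma, number of branches (maximal unbranched
paths, counting the root segment as one) and maximum branch order
(bifurcations crossed from the root). "Euclidean distance" is read as
the maximum over nodes of distance to the soma. PCA alignment rotates a
point cloud onto its principal axes ordered by decreasing span, fixes
each axis's sign by making its largest-|loading| coordinate positive
(for reproducibility), and translates the soma to the origin.
Feature-wise z-scoring uses the sample (n−1) standard deviation;
constant columns become zero with a warning.

## Neuron-beta

For a group of mesoscale experiments with mean projection vector
M = [m₁…m_p] and a single cell S = [s₁…s_p] over the same structures,

    neuron-beta = Cov(M, S) / Var(M),

the regression slope of the cell on its population pattern: 1 for a
perfectly proportional cell, a for S = a·M + b. Var(M) = 0 is an error.

## Clustering procedures

**Projection-space clustering** (used for highly divergent projection
classes): strength vectors → PCA keeping > 90% of variance → 2D UMAP
(`n_neighbors` = 15, seeded) → agglomerative Ward clustering of the
embedding, cut at a configured dendrogram distance (default 10; the cut
stands in for a manual dendrogram read, and a cluster count can be given
instead). Identical inputs short-circuit to a single cluster.

**SNN consensus co-clustering** (used for the corticoclaustral analysis
with four feature sets: projection pattern, soma location, axon and
dendrite morphology): per feature set, Euclidean distances give each
sample a ranked k-nearest-neighbour list (k = 10 default); the
similarity of two samples is the best average rank of a shared
neighbour,

    S(i, j) = max over shared v of { k − ½·[rank_i(v) + rank_j(v)] },

zero when the lists are disjoint (an `as_printed` switch reproduces an
asymmetric variant that halves rank_j once more). Each of 1,000
iterations draws 95% of the samples, builds the SNN graph and runs
fast-greedy community detection (python-igraph); a pair's co-clustering
score is the number of times co-clustered over times co-sampled. The
consensus is the weighted mean over feature sets (equal weights by
default, configurable since no canonical weights exist). Average-linkage
agglomerative clustering on 1 − consensus (cut at 0.5 or a requested
count) yields clusters; each sample's within-cluster distances are then
compared with the pooled within-cluster background by a one-sided
Mann-Whitney test (α = 0.01, no multiplicity correction) and significant
samples are removed, re-clustering until a fixed point. Clusters below
the minimum size (3) are reported unassigned. With many samples the
Mann-Whitney prune is deliberately aggressive — any sample whose
consensus membership is merely fuzzy is significant — which trims
boundary cells but leaves cluster identities intact.

**Arbor typing**: arbor features (2D area, total length, radius, depth
mean/sd) → z-score → PCA to 95% variance → UMAP → k-means (k = 2),
cluster ids ordered by mean radius so type 1 is the smaller-arbor type.

## Topography and overlap

Arbors are voxelized as cable-length maps on a coarse grid (50 µm);
overlap is the length-weighted Dice score
`2·Σ min(a,b) / (Σa + Σb)` — the field reports overlap without
defining a formula, so the choice of Dice is declared here, with the
grid size configurable. Pairwise analyses fit (i) arbor centre distance
against soma distance by least squares (free and zero intercept) and
(ii) an exponential overlap decay `a·exp(−b·d_soma)` by log-linear
regression over positive overlaps. Overlap-based domains come from
average-linkage clustering on 1 − overlap. The soma→arbor topographic
map is summarized by the 3×3 Pearson correlation between soma and
arbor-centre axes; the axis pairing maximizes Σ|corr| exactly over the
six permutations, and each pair carries its correlation's sign — a
preserved map reads as the identity pairing with positive signs, a
dorsoventral flip as a negative sign on that axis, and a projection
rotation as a permuted pairing.

## Synthetic data

The generators emulate only what the analyses assume, deterministically
per seed:

* **Toy atlas** — a layered cortical slab (L1, L2/3, L4, L5, L6 and
  white matter at 100/150/100/150/150/100 µm) split into two areas over
  six subcortical boxes, 25-µm voxels, midline at the centre; every
  voxel label rolls up to one of 8 curated structures.
* **Planted-arbor neurons** — each arbor is a Gaussian cloud (60 nodes,
  ~50 µm radius) whose nodes attach to their nearest predecessor; arbors
  connect to the soma arbor through sparse bridge paths whose soma-side
  segment is longest, so the minimum-similarity cut severs the bridge at
  its first gap and ground-truth labels are unambiguous. Centroids are
  rejection-sampled to at least 5× the arbor radius apart (≥ 250 µm),
  the separation regime the detection guarantees address.
* **Projection populations** — archetypes are sets of target structures
  with mean axon lengths; each cell keeps each target with probability
  1 − dropout (0.25 default, ≥ 1 target always kept) and draws lengths
  with log-normal noise (σ = 0.3), so each cell selects a subset of its
  population's targets while the pooled population recapitulates the
  archetype. Mesoscale NPV rows are population mean lengths scaled into
  the NPV range with log-normal noise (σ = 0.2).
* **Feature-set populations** — four matrices sharing one planted
  partition (cluster centres 6 within-cluster-σ from the origin in
  independent directions per set), with optional far outliers placed
  away from every centre.
* **Topographic populations** — somas uniform in a box, arbor centres a
  planted linear map of the somas plus isotropic noise; optionally a
  planted pairwise overlap matrix decaying exponentially in soma
  distance for decay-rate recovery.

What the synthetics do **not** emulate: realistic branching statistics,
boutons, curved cortical sheets, registration error, or
reconstruction noise. Passing tests therefore demonstrate algorithmic
correctness and recoverability under the stated planted conditions, not
performance on real reconstructions.

## Problem sizes and determinism

The test-suite and acceptance script run planted-arbor recovery over 51
neurons (~180 nodes each), cut-optimality checks against exhaustive
enumeration on 30-node trees, co-clustering at the full 1,000 × 95%
resampling on 61-sample populations, and topography recovery over 100
seeds — sizes chosen so the whole suite completes in about a minute on
one core while the checks remain exhaustive where an oracle is
enumerable. Every stochastic step (UMAP, k-means, resampling, the
generators) takes an explicit seed; embeddings are contract-tested
(separated blobs stay separated, same seed ⇒ identical output) rather
than value-tested.

## Known limitations

* Arbor-count selection is silhouette-based; arbors that are spatially
  interdigitated (silhouette-poor) fall back to a single arbor even when
  topologically distinct.
* With σ = 1 the edge similarity `exp(−d)` underflows for segments
  longer than ~745 µm; cuts among such edges tie at zero weight and
  resolve by the deterministic lexicographic tie-break. Use σ on the
  order of the segment length when absolute weights matter.
* The Mann-Whitney outlier prune tests each sample against the pooled
  background without multiplicity correction; at α = 0.01 it removes
  fuzzy boundary samples liberally on small datasets.
* Mesoscale NPV is consumed as a table; nothing here derives it from
  images, and bouton-level target calls use axon tips as a stand-in.
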