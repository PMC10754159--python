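# Methods

## Morphometry

Each segmented cell is described by 33 size/shape parameters: 14 per
compartment (cell, nucleus) — area, perimeter, form factor 4πA/P²,
eccentricity, solidity A/A_hull, extent A/A_bbox, major/minor axis
lengths (from the second central moments), aspect ratio, equivalent
diameter 2√(A/π), max/min Feret diameter, compactness P²/(4πA), convex
area — plus five cross-compartment values: nucleus/cell area and
perimeter ratios, nuclear centroid displacement (absolute and divided
by the cell equivalent diameter) and cytoplasm area. Orientation is
deliberately excluded: it is sign-valued, and the normalization
contract (below) requires positive or ratio-bounded features.

Numerical choices:

* **Perimeter** is the arclength of the outer marching-squares contour
  at level 0.5, simplified by Douglas–Peucker with 1 px tolerance
  before summing segments. The raw staircase contour overestimates
  smooth boundaries by ~6%; the simplified polygon is within ~2% of the
  true arclength for discs of radius ≥ 10 px and converges with size.
  Consequence: perimeter-derived values are invariant under 90°
  rotation only to ~10⁻⁴ (contour tracing starts at an
  orientation-dependent pixel); all other features are exactly
  invariant.
* **Feret diameters** are computed on the convex hull of pixel-corner
  points: the maximum caliper as the hull diameter, the minimum as the
  smallest width across hull-edge normals (exact for convex polygons).
* **Degenerate regions**: a one-pixel-wide region has zero
  moment-based minor axis; it is floored at 1 px so the aspect ratio
  stays finite.
* **Pairing** of nuclei to cells on real data uses maximal pixel
  overlap, ties toward the smaller label; synthetic masks guarantee
  matching labels and containment. Empty compartments are skipped with
  a log entry; nuclei disjoint from their cell are flagged and
  excluded.
* **γH2AX** is the mean nuclear intensity of the damage channel with
  pixel values normalized by the bit-depth maximum (2^depth − 1), i.e.
  the sum of normalized pixel values divided by the nuclear pixel
  area; always in [0, 1].
* Pixel coordinates are 0-based row/column; areas are px² (a physical
  calibration is out of scope).

Discretization sets the practical accuracy floor: on shapes ≥ 30 px
diameter, scale covariance holds within 2% and arbitrary-rotation
invariance within 3%; thinner shapes degrade roughly like
perimeter/area.

## Normalization

Features are transformed per column as `x → log10(x + ε)`, then
z-scored against the fitting set using the population (ddof = 0)
standard deviation. ε defaults to 10⁻⁶ and is applied only to
ratio-type features that can legitimately reach zero (eccentricities,
centroid displacements, cytoplasm area); strictly positive features use
ε = 0, and a nonpositive value there raises an error naming the
feature. Constant columns map to all-zeros and invert back to their
constant. The fitted transform (ε, mean, sd per feature) is stored and
reusable; the round trip inverts to 10⁻⁹ relative error.

Log-transforming before standardization makes heavy-tailed size
features comparable to bounded shape ratios; z-scoring puts all 33 on a
common scale so no feature family dominates distances by units alone.

## Embedding

UMAP (n_neighbors = 30, min_dist = 0.1, fixed seed) reduces the
normalized 33-space to 2-D. Raw UMAP axes are arbitrary, so the output
is post-processed by an axis swap/flip convention: the axis more
strongly (Spearman) associated with cell area becomes axis 1, flipped
so the correlation is negative; axis 2 is flipped so its correlation
with cell aspect ratio is positive. Size then decreases to the right
and elongation increases upward, giving every embedding the same
reading. If fewer cells than n_neighbors are supplied the parameter
shrinks with a warning.

## Choosing k and the cluster-groups

For each candidate k in the scanned range, k-means (k-means++, 50
restarts, tolerance 10⁻⁶) records inertia and mean silhouette (on a
seeded subsample of ≤ 2,500 cells for tractability). The selected k is
the knee of the inertia curve — the point of maximum perpendicular
distance to the chord across the scanned range, both axes min–max
normalized. Exact ties break toward the first candidate whose
silhouette change has flattened (|Δs| < 0.01), then toward smaller k.
A curve whose maximal chord distance stays below 0.1 has no distinct
knee (a single structureless blob bends gently everywhere); selection
is then flagged and the range minimum returned with diagnostics. The
full trace (inertia, silhouette, chord distance per k) is part of the
result for audit.

Cluster ids are renumbered in decreasing mean cell area, so cluster 1
always denotes the largest-cell morphology and reports are comparable
across runs. Cluster-groups come from Ward linkage on the k cluster
mean signatures, cut either at a requested group count or automatically
at the largest gap between successive merge heights; CG ids follow the
same size ordering (CG1 = largest). The auto cut is exposed because the
choice of three groups is a property of the data's merge structure, not
a constant of the method.

## Profiles, entropy, damage

Per (population, condition) the cluster fractions p and their
aggregation over cluster-groups are computed over the *global* k
clusters — clusters absent from a condition contribute 0, so entropy
`S = −Σ pᵢ ln pᵢ` (zero terms defined 0 by continuity) is always
comparable across conditions with bounds [0, ln k]. Natural log is the
default; the base is configurable since only relative comparisons are
used. The enrichment matrix collects each condition's fraction vector
as a column (columns sum to 1) with rows in Ward dendrogram order;
damage maps are arithmetic means of γH2AX per cluster with cells pooled
across conditions (missing values excluded and counted). A Pearson
helper (r with two-sided t-test p) serves summary-table correlations
such as damage versus dead-cell fraction.

## Susceptibility score

`S_SC = [(CG1_UL − CG1_C) − (CG1_UH − CG1_UL)] / (CG1_UH − CG1_C)`,
implemented alongside its monotone closed form (a − b)/(a + b); both
agree to 10⁻¹² and the bounds ±1 are attained exactly when the whole
CG1 decline happens at one dose step. A zero denominator (CG1 unchanged
control→high) is an undefined score and is reported as such per
population rather than silently dropped. Non-monotone trajectories
(CG1 rising at low dose) are scored but flagged, since the formula's
meaning is only established for declines. Parental normalization is
subtraction (parental ↦ 0): scores are signed and can sit near zero,
where a ratio would be unstable; division remains a config choice a
user could implement downstream. Ranking is by descending normalized
score with deterministic id tie-breaks; an optional percentile
bootstrap (resampling cells within each dose) attaches 95% intervals
as an extension beyond the point score.

## Dose conversion

Areal dose (µg/cm²) = concentration (µg/mL) × medium volume per growth
area (mL/cm²). The default geometry 0.2816 mL/cm² is back-computed so
the two standard exposure concentrations 125 and 500 µg/mL correspond
to 35.2 and 140.8 µg/cm²; it is a config field, not a constant.

## The synthetic-data generator

The generator emulates the study design of a PM-exposure profiling
experiment: ten morphological archetypes organized in three
cluster-groups, condition-dependent redistribution among them,
subtype-linked damage, and clone panels with planted dose-response
shifts.

**Shape model.** A cell is an ellipse (area and aspect ratio sampled
per subtype, lognormal) perturbed by a radial harmonic
`r(φ) ∝ 1 + α cos(mφ + φ₀)`, rescaled so the target area is preserved;
the amplitude α is obtained from the subtype's target solidity by
inverting a numerically tabulated solidity(α) curve per harmonic
order. Cells use order m = 3 (three broad lobes, the classic
spread-cell silhouette); nuclei use order m = 6, because an order-m
boundary stays convex below amplitude 1/(m² − 1) and reaching nuclear
solidities of 0.91–0.99 at order 3 would take amplitudes large enough
to distort the nucleus's moment-based shape readouts and its fit
inside the cell, whereas order 6 reaches them with a gentle ruffle.
The nucleus has its own aspect ratio and solidity and is displaced
along the cell's major axis by a Rayleigh-distributed fraction of the
cell diameter, capped at 80% of the free run between nucleus and cell
tips (the cap accounts for the inward reach of the cell's lobes). A
width-fit rule shrinks any sampled nucleus whose width (including its
ruffle) exceeds 95% of the cell's worst-case inner width — otherwise
rendering would truncate it against the cell boundary and bias its
moment-based shape readouts; the rule is a deterministic function of
the latents, so both output routes apply it identically. Rendered
nuclei are additionally clipped to their cell, guaranteeing
containment. γH2AX is a clipped normal per subtype, rendered as a
constant nuclear intensity in the damage channel — recovery by the
morphometry stage is then exact up to 16-bit quantization, which keeps
the generator's damage ground truth unambiguous.

**Two output routes.** Populations can be emitted as feature tables
(closed-form geometry evaluated on the same boundary polygon the mask
route rasterizes — perimeter, bounding box and Feret calipers are
computed from that polygon, vectorized over cells) or as 16-bit label
TIFF fields (2048² default, rejection-sampled non-overlapping
placement, placement error when density exceeds capacity). Both routes
consume identical latent draws, so subtype feature means agree between
them within 10% at n ≥ 500 (verified in the suite); residual
differences are rasterization bias. Nuclear centroid displacements are
sub-pixel to a-few-pixel quantities, so their recovery is compared
against a 1 px floor — the centroid of a rasterized, boundary-clipped
region is simply not defined more finely.

**Default fixture.** Ten subtypes in three CGs — CG1 {1, 2, 5} largest
and low-damage, CG2 {3, 4, 6} intermediate and elongated (subtype 4
lowest damage), CG3 {7–10} smallest and roundest (9, 10 highest
damage); cell area decreases strictly with subtype id so size-ordered
cluster renumbering recovers the planted ids. The archetypes differ
along seven latent axes (size, cell elongation/solidity, nucleus
fraction/elongation/solidity, nucleus off-centering). Their values
were designed so that, after normalization, the ten subtype centroids
sit at comparable separations in many directions of feature space with
subtypes of a CG mutually closer than subtypes across CGs. This
geometry is what makes the planted structure recoverable by the
methods under test: when a single dominant size gradient carries the
subtype structure (the obvious naive design), the inertia-knee
criterion locks onto the coarse group level instead of the planted k,
and the fixture cannot test what it plants. Within-subtype CVs are
5% (area, aspect ratio) with small absolute jitters on solidity and
nucleus fraction — tight but within the spread of clonal epithelial
populations. Five default conditions (control, urban-like low/high,
fine-like high, diesel-like high) redistribute fractions so high-dose
urban/fine conditions enrich the small round subtypes 9–10 and the
diesel-like condition enriches the elongated 4 and 8.

**Clone panels.** A clone is a baseline composition over the three CGs
plus a shift profile (a, b): the CG1 fraction drops by a at control→low
and b at low→high, with the displaced mass moved 30%/70% into CG2/CG3.
Ground-truth CG1 fractions are (c, c − a, c − a − b) and the planted
score is (a − b)/(a + b); the default panel of parental + four clones
has strictly ordered planted scores for rank-recovery tests.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: staining texture and artifacts,
segmentation errors, cell–cell contact and confluency effects,
imaging noise in the damage channel, batch effects, and real
morphological continua (planted subtypes are discrete modes; real
populations blend into each other). Results on the fixture demonstrate
correctness of the computations, not robustness to microscopy
pathology.

## Problem sizes and determinism

Default analyses run at ~10⁴ cells; the suite uses 10³–10⁴ per test
and renders masks at a few hundred cells per field set. All sampling
goes through seeded numpy Generators; a fixed config and seed
reproduce every CSV byte-for-byte (floats are written at 10
significant digits). k-means uses 50 restarts and UMAP a fixed
random_state, so the full pipeline is deterministic per (config,
seed).

## Known limitations

* The 33-parameter list fixes one concrete reading of the AreaShape
  family; pipelines built on a different supplement-exact list will
  differ in detail, though the pipeline only requires 33
  positive/ratio-bounded features.
* The knee+silhouette rule is a deterministic surrogate for a visual
  "plateau" judgment; near-degenerate curves can put the knee one k
  away from intuition. The selection trace is emitted precisely so
  such calls can be audited.
* Entropy comparisons across datasets with different k are not
  meaningful (bound is ln k).
* The susceptibility score is undefined for CG1_UH = CG1_C and only
  interpretable as a susceptibility contrast for monotone declines;
  the flag column must be consulted before reading rankings.
* Mask rendering targets clean, well-separated cells by design;
  it cannot stress segmentation-error handling beyond
  label-consistency contracts.
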