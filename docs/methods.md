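# Methods

This note documents the models and procedures implemented in `craterscope`,
the parameters that matter, the numerical conventions, and what a passing
test on synthetic phantoms does and does not establish.

## Coordinates, units, calibration

All internal coordinates are 0-based array indices; all exported quantities
are physical (μm, mm², cells/mm², counts/cm) with the origin at array index
(0, …, 0). Readers refuse to operate without a physical pixel/voxel size:
an image with no spacing metadata and no explicit override raises an error
rather than assuming a unit, because published acquisition notes for this
kind of data are inconsistent about mm vs μm at exactly the point where a
silent guess would corrupt every downstream area and distance.

## 3D crater segmentation (black top-hat)

The tumor mask is `largest_cc(otsu(gaussian(channel)))`, with an optional
bright-cell exclusion mask subtracted before component analysis. Craters are

    craters = open( close(T, K_c) \ T , K_o ),   K_c = 40³, K_o = 2³ voxels,

the black top-hat of the binary tumor segment: closing fills concave surface
indentations smaller than the kernel, subtraction isolates them, and the
small opening removes residue from the mismatch between tumor morphology and
the cube kernel. Conventions that make this bit-stable:

* **Kernels are cubes in voxel units** (not μm); an option to scale the
  z-extent for anisotropic stacks exists but the default follows the stated
  voxel-based recipe.
* **Even kernels** are centered at floor(k/2). The paired erosion uses the
  reflected structuring element (implemented as a one-voxel shift of the
  separable min/max filters), so closing is extensive and opening
  anti-extensive exactly; the test suite verifies bit-equality against an
  independent shift-and-OR/AND oracle.
* **Borders**: the volume is padded with background by the kernel size before
  closing and cropped afterwards, so image edges cannot produce phantom
  craters. Crater instances touching the volume border are flagged.
* Instances below 27 voxels (3³) are discarded; the floor stabilizes counts
  against single-voxel residue.

A property worth knowing: a notch wider than the closing kernel in *both*
lateral axes is not filled at all (the structuring element escapes through
the mouth), so such a gap contributes no crater volume. Crater detection is
therefore scale-limited by the kernel, exactly as in the original recipe.

Cell detection is multiscale Laplacian-of-Gaussian with scales expressed in
μm and converted per axis through the voxel spacing (defaults 3–8 μm,
T-cell radius scale). The proprietary blob detector it replaces has
unpublished parameters; equivalence is claimed at the contract level
(recall/precision ≥ 0.95 on phantoms at SNR 10), not operator level. The
bright-cell "normalization" step is percentile rescaling, and detected
bright blobs must additionally stand ≥ 8 robust standard deviations (MAD)
above the channel median — without this floor, a channel containing nothing
but noise would yield spurious exclusions after rescaling.

## Region statistics

* **Assignment**: a cell is *crater* if its centroid lies in or within
  `contact_dist` of a crater voxel, else *tumor* under the same rule, else
  *outside* (priority crater > tumor). `contact_dist` defaults to 0
  ("direct contact"); the separate 5 μm near/far convention is exposed as a
  boolean column rather than mixed into the assignment. Distances come from
  exact Euclidean distance transforms with anisotropic sampling.
* **Surface areas** are measured on a marching-cubes isosurface of the tumor
  mask (robust to anisotropy; voxel-face counting overestimates tilted
  surfaces by up to ~50%). Triangles within one voxel of a crater voxel are
  attributed to the crater lining, the rest to the free tumor surface. On
  hemispherical-pocket phantoms this recovers the analytic lining area
  2πr² to a few percent, with a small positive bias from rim triangles.
* **Coverage** = crater footprint / (tumor + crater footprint) on the
  projection along the imaging axis, × 100. The denominator *includes* the
  crater area itself (the alternative — craters over crater-free surface —
  is a one-line change; the projected-footprint reading makes coverage
  insensitive to pocket depth, which the top-hat only partially recovers).
  Per-crater diameter is the equivalent-circle diameter of the projected
  footprint; max-Feret is deliberately not the default because it is noisier
  under pixelation.
* **Group tests**: Mann-Whitney U is exact (full enumeration) when both
  groups have n ≤ 8 and no ties, otherwise the normal approximation with tie
  correction; t tests are two-sided, paired or unpaired. Degenerate inputs
  are explicit: all-tied MWU returns p = 1 with a warning; a zero-variance
  separation reports the limit (|t| = ∞, p = 0) with an
  `exact_separation` flag. Note that at n = 8 per group the
  continuity-corrected normal approximation can deviate from the exact MWU
  p by up to 0.0109 (mid-range p ≈ 0.44); the exact branch exists precisely
  because the approximation is not yet uniformly accurate at that size.

## RNAscope

Projection is a per-channel maximum over z. The foci filter keeps focus *i*
iff ≥ `min_neighbors` (2) other foci lie within `neighbor_radius` (10 μm) —
boundary inclusive, exact pairwise distances (KD-tree accelerated, verified
against the O(n²) oracle). The density map is a sum of isotropic Gaussians
with a **fixed physical bandwidth** (default 5 μm, half a T-cell diameter —
the transcript-cluster scale; the source recipe does not state one), each
kernel renormalized to unit mass over the image grid so the map integrates
exactly to the foci count regardless of edge proximity. This is why the map
is an explicit kernel sum and not a covariance-scaled KDE, which would
silently rescale the stated bandwidth. Cells are local maxima of the map;
peaks must exceed a density floor of 2.5 foci-equivalents at the kernel
center (≈ 2.5/(2πσ²)), so isolated residual foci do not become cells. Two
clusters closer than the peak separation (8 μm) merge into one call.

The tumor mask is smoothing + Otsu + closing (the proprietary
membrane-based segmentation is replaced at the contract level), and the edge
band is defined metrically: pixels with 0 < d ≤ 15 μm from the tumor under
the exact distance transform. Transcript-to-cell association assigns each
focus to its nearest cell within the association radius (default: the median
called-cell radius); exact ties break toward the lower cell id. Percent
ifng⁺ is reported over three zones: crater, tumor border (0–50 μm from the
tumor surface, either side), tumor interior.

## Attrition surface

Fragment centroids (per-label center of mass, μm) are fitted with a
bivariate polynomial z = P(x, y); x and y are affinely rescaled to [-1, 1]
for conditioning. In-sample RMSE decreases monotonically with degree, so
"best fit" is operationalized as 5-fold cross-validated RMSE with a
one-standard-error tie-break toward the *lower* degree; the tie tolerance
has a small absolute floor (10⁻⁹ of the z scale) so that noiseless
polynomial data — where all candidate degrees reach machine-precision CV
error — resolves to the true minimal degree. Candidate degrees whose
coefficient count exceeds the sample size are dropped and noted. A
rank-deficient design (collinear x, y) is an error naming the degeneracy.

Projection: the surface domain is the convex hull of the centroid (x, y);
it is discretized into `grid_cell` (10 μm) cells and a cell is occupied when
any fragment footprint — a disk of that fragment's equivalent-sphere radius —
covers the cell center. Attrition = 100 × unoccupied / total cells.
Centroid-only projection is available (`footprint="point"`); reports name
the mode. Attrition is invariant under uniform coordinate scaling (with the
grid scaled along) and can only grow when fragments are removed.

## Human mIF

Channels are normalized to their 99th-percentile value — taken as the
empirical order statistic, not the interpolated quantile, which makes the
normalization exactly idempotent — clipped at 1, and membrane channels are
summed into a composite; the nuclear channel is normalized separately.
Background subtraction is a rolling ball (grayscale opening with a ball
element, radius 50 px).

Region logic: tumor = Otsu → closing → opening on the tumor channel; margin
= the band within `margin_width` (40 μm) outside the filled tumor; holes
fully enclosed by the tumor are filtered by area (≥ 2000 μm²) and mean CD31
content to label **perivascular areas** (both thresholds are unstated in the
source procedure and are exposed parameters with logged defaults). The
**PMB length** of each perivascular area is measured on its boundary after a
morphological opening at half the maximum crater size (25 μm radius) —
crater notches are protrusions of the hole region, and the reference curve
should span their mouths the way an annotator would draw it, otherwise every
crater would lengthen the very boundary it is normalized by — followed by
Gaussian smoothing (5 μm) and sub-pixel contouring, since raw digital
contours overestimate length. On disc phantoms this recovers 2πr within 3%.

The rule classifier accepts a candidate gap iff: on a stromal-melanocytic
boundary (within 15 μm of a PMB or outer-border contour); equivalent
diameter in 20–50 μm; ≤ 2 collagen fibers (skeletonized collagen-positive
components crossing the polygon — an automatable proxy for visual fiber
counting); nuclear density < 50% of the sample's perivascular stroma density
(the reference rule says only "low … compared to the perivascular stroma";
the quantile is a parameter); no CD31/CD105-positive vessel content; no
αSMA content. Rejections name the failed rules, and the classifier is
monotone: relaxing any single threshold can only grow the accepted set.
Cell phenotyping is a deterministic priority-ordered gating table
(Treg ≻ CD8 T ≻ DC ≻ CD4 T ≻ tumor ≻ other) with a passthrough for external
cluster labels; manually corrected clustering is not reproducible and is
out of scope. Cell region assignment uses the exclusion priority
crater > border > tumor > outside. Linear density = accepted craters / PMB
length (cm), with flagged fibrotic segment lengths subtractable from the
denominator.

## Concordance

Pairwise instance matching between annotator masks: all overlapping label
pairs get a Jaccard index from a joint histogram; pairs with JI **strictly**
greater than 0.4 are candidates; one-to-one resolution is greedy by
descending JI (ties toward lower ids), with Hungarian optimal assignment as
an option — greedy is the documented default and agrees with optimal on
small instances in ≥ 95% of random phantoms. Unmatched first-mask objects
are FP, unmatched second-mask objects FN; F1 is the harmonic mean of
precision and recall and the report averages F1 across pairs (pairs with no
objects on either side are excluded with a warning). Swapping the masks
swaps FP and FN and leaves TP and F1 unchanged. Polygon annotations are
rasterized on the image grid before matching.

## Synthetic phantoms: what they emulate, and what they do not

Every generator is a pure function of (parameters, seed) — same inputs,
bit-identical outputs — and every manifest quantity is computed analytically
or by direct counting on the planted geometry, never by the analysis code
under test.

* **3D tumor**: a slab filling the lateral field with hemispherical pockets
  (diameters ~N(50, 8) μm by default, matching the reported fish niche
  scale; depth = half the diameter) carved into the top face; Gaussian
  spherical cells (10 μm diameter) placed inside pockets, just under the
  free surface, or embedded at depth; tubular vessels; additive Gaussian
  noise on a constant background (no shot noise, no PSF, no attenuation
  with depth, no pigment absorption). Density-ratio phantoms compute cell
  counts from the analytic areas (pocket lining 2πr², free top surface), so
  the planted ratio is exact.
* **Foci**: Gaussian clusters (σ = 2 μm, ≥ 100 μm apart, 4σ inside the
  field) plus uniform noise.
* **Surface**: centroids on a planted polynomial over [0, 1000]² μm
  (coefficients in scaled coordinates; top-order terms forced to 3–8 μm
  amplitude so the planted degree is identifiable over 1 μm noise), with an
  interior disk of the complementary area left empty; fragments keep their
  footprint radius clear of the disk boundary so planted attrition is exact
  up to grid discretization.
* **Annotators**: rectangle pairs shifted to achieve each requested JI
  within integer-pixel granularity (±0.02, recorded), plus disjoint extras.
* **mIF**: a tumor disc with three perivascular holes (r = 60 μm, CD31
  cores, stroma nuclei at 0.004/μm²), two rule-satisfying crater notches
  per hole, and one decoy per rule (oversized on the outer border;
  vessel-, fiber-, nuclei- and αSMA-bearing on a hole boundary; one gap deep
  in the tumor interior). Class marker intensities are ≥ 10 noise SD above
  background.

A green test on these phantoms establishes that the implementation computes
the stated quantities correctly on geometry where the truth is known. It
does **not** establish robustness to real-microscopy nuisances — depth-
dependent attenuation, pigment shadows, segmentation errors in the provided
cell masks, irregular niche shapes, or annotator ambiguity — and the
headline biological effect sizes of the original study are properties of
real tissue, not of these phantoms.

## Known limitations

* Crater detection inherits the closing-kernel scale limit; gaps wider than
  the kernel in both lateral directions are invisible to the top-hat.
* Greedy instance matching is an approximation to optimal assignment
  (documented, optional exact mode).
* The collagen fiber count is a skeleton-component proxy for visual fiber
  counting.
* The mIF hole detector finds only holes fully enclosed by tumor in the
  section plane; perivascular areas opening to the section edge are not
  labeled.
* No deconvolution, registration, or time-lapse tracking; longitudinal
  comparisons are consumed as paired scalars (areas, densities) only.
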