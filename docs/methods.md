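# Methods

This note records the models implemented in `qaamp`, the assumptions they
make, the defaults chosen where the underlying method leaves a choice open,
and what the synthetic phantoms do and do not establish about behavior on
real CT data.

## Coordinate and data conventions

Volumes are `(x, y, z)` float arrays of Hounsfield units with axis 2 the
axial (slice) direction; voxel `(i, j, k)` has its center at
`origin + index·spacing` (mm). All geometry — morphometry, mapping,
resistance, OLVP — is computed in this physical frame. Annotation
coordinates are 0-based voxel indices; conversion to mm happens at use
sites via the volume's spacing. Ellipse interiors use the inclusive rule
`((x−cx)/(w/2))² + ((y−cy)/(h/2))² ≤ 1`.

## Annotation model and adjudication

A plug is a set of per-slice axis-aligned ellipses sharing a
`(reader, plug_label)` pair. Concordance between two readers is not
defined by the annotation format itself, so the package uses the simplest
testable surrogate for visual matching: two plugs match when their
stacked-ellipse interiors share at least one voxel on at least one common
slice, with candidate pairs resolved greedily by descending overlap (ties
to lower labels). Consensus keeps reader A's geometry by default
(`geometry="union"` keeps both readers' slices, preferring A where both
annotated); single-reader plugs enter the consensus only when the
adjudicator accepts them. Burden scores are computed from the consensus:
slice score = ellipse count, plug score = distinct plug count, segment
score = distinct bronchopulmonary segments containing a plug, capped at
20. Whether slice score should instead sum per-reader annotations is
ambiguous in the source protocol; counting consensus ellipses is the
choice here because all downstream quantities use the finalized
annotation.

## Segmentation

Each plug's ROI voxels (union over its slices) are clustered into two
groups by Gustafson–Kessel fuzzy clustering on scalar intensity with
fuzzifier m = 2, tolerance 1e-5 on the maximum membership change, at most
100 iterations, and a per-cluster variance floor of 1e-6 × the data
variance. Centroids initialize at the 10th/90th intensity percentiles
(deterministic; the seed only matters if those coincide). In one
dimension the GK unit-volume metric normalization exactly cancels the
cluster variance, so the induced distance is Euclidean — the method
reduces to fuzzy c-means while still reporting per-cluster variances.
Consequences used by the tests: memberships are invariant to affine
intensity maps `a·HU + b, a > 0` (the segmentation needs no HU
calibration), and the objective is non-increasing across iterations
(alternating minimization). Defuzzification is by maximum membership with
ties to the brighter (foreground) cluster, biasing toward plug recall;
connected components use 26-connectivity because plugs traverse slices
obliquely; the largest component by voxel count is the plug, with no
minimum size. Constant-intensity input is a degenerate-input error, not
an empty mask. The clustering runs per plug subset, not per scan.

## Morphometry

Coordinates are voxel centers without partial-volume weighting; the
covariance uses denominator n (population form) to match the `4·√λ`
length convention. For a uniform rod of length l the axial variance is
l²/12, so the length estimate is `4·l/√12 ≈ 1.155·l` — a convention (two
standard deviations each side of center), not an unbiased ruler; tests
assert the convention's value, 23.09 mm for a 20 mm rod. The diameter
estimator fixes the axis to the principal eigenvector through the
centroid and sets `R̂ = √(2·mean d⊥²)`, exact in expectation for a
uniform solid cylinder (`E[d⊥²] = R²/2`); the result is floored at the
in-plane voxel size so a single voxel reports a physical width. Voxel
volume (count × voxel volume) is the canonical plug volume; mesh volume
is also available from the marching-cubes surface. Meshes are computed on
the zero-padded binary mask at level 0.5 and optionally smoothed with
Taubin's two-step band-pass filter (λ = 0.5, ν = 0.53, 10 iterations),
which preserves vertex count and approximately preserves volume (a
digital ball of radius 5 mm at 0.5 mm voxels meshes within ~1% of
4/3·π·r³).

## Airway mapping

Plugs are localized by the nearest airway termination point in Euclidean
distance from the plug mask centroid (the centroid is stable and
testable; the alternative — nearest surface voxel — is not clearly better
and is harder to reproduce). Generation and lobe are inherited from the
terminal branch owning that termination. The search is unrestricted by
lobe; only OLVP applies the lobar restriction. Distance ties break to the
lowest branch id. This mapping is exact on phantoms because the phantom
generator returns an *observed* tree pruned distal to every plug: a fully
occluded branch is the end of what a lumen segmentation can see, so the
plugged branch is terminal and owns the termination nearest the plug.

## Resistance score

Each branch is a Poiseuille element `R_n = 8·μ·L_n/(π·r_n⁴)` (SI units;
branch length and the single stored mean lumen radius in mm are
converted). Node pressures solve Kirchhoff balance with the inlet at
ΔP = 1 Pa, open terminal outlets at 0 Pa, and plugged terminal branches
removed — removal is the natural zero-flow boundary and is equivalent to
forcing zero flow at those outlets. The effective resistance is
ΔP/Q with Q the inlet flow; `RS = 100·(R_p − R_a)/R_a`. μ defaults to
1.85e-5 Pa·s (humidified air at body temperature); both μ and ΔP cancel
in RS and are asserted irrelevant over random configurations. When every
outlet is plugged the score is flagged infinite rather than reported. A
singular system outside that case raises a structured error instead of
silently omitting the scan. The linear solve is validated against an
independent recursive series–parallel reduction (prune plugged leaves,
parallel-combine children, add the parent in series) to 1e-9 relative on
1,000 random trees.

RS per plug is defined per generation group (proximal ≤ 7, intermediate
8–9, distal ≥ 10): the RS recomputed with only that group's plugs,
divided by the group's plug count. The end-to-end phantom places its
plugs in generations 2–6, which all fall in the proximal group, so its
proximal-vs-distal contrast is computed between the most proximal and
most distal *plugged generations* with the same machinery; the ordering
(generation-2 plugs carry 300–900× the per-plug RS of generation-6 plugs
on these trees) is insensitive to this choice.

## OLVP

Voxel-to-terminal assignment is an exact nearest-neighbor query of voxel
centers against same-lobe termination points (KD-tree; no approximation
at phantom scales), so lung tissue is never assigned across a fissure. A
lobe present in the label map but lacking terminations is an error naming
the lobe — the phantom generator can produce this when a plug sits above
the lobe-root generation, which is why the end-to-end phantom uses four
lobes rooted at generation 2. Obstructed plus unobstructed volume equals
lobe volume exactly, and whole-lung OLVP is the volume-weighted mean of
lobar values.

## Length phenotypes and mixture selection

Phenotype classification is a fixed threshold: stubby ≤ 12 mm < stringy.
The threshold is a configuration constant, deliberately not re-derived
from each dataset's mixture fit. The mixture machinery fits k = 1…5
Gaussians by EM with 10 restarts (k-means++-style hard partition
initialization per restart — means, spreads and fractions from the
partition blocks), tolerance 1e-6 per sample on the log-likelihood,
at most 500 iterations, and a variance floor of 1e-4 mm²; the minimum-AIC
fit (AIC = 2·(3k−1) − 2·lnL) is selected. A diverse-restart
initialization was rejected: it reliably finds degenerate
narrow-component optima whose likelihood gain defeats the AIC penalty,
which is the classic unbounded-likelihood pathology of Gaussian mixtures,
whereas k-means initialization targets the clustering-structured optima
the model-selection question is about. Even so, AIC is known to
overselect mixture order: on 100 simulations of a well-separated
two-component mixture (n = 500) the k = 2 fit wins ~91% of seeds and a
spurious third component wins the remainder by > 3 nats. The selection
*rate* is therefore reported as a measured quantity rather than asserted
at an idealized level; recovered component means are within 10% of truth
whenever k = 2 is selected.

## Longitudinal tracking

"Same airway" across timepoints means the same branch id (phantoms share
one tree; for real trees with unstable ids the branch path signature
would serve, but that case is out of scope here). Matching is one-to-one;
when two follow-up plugs occupy one branch the nearest centroid wins and
the other is reported as new. Persistent plugs carry length/volume
deltas; the delta summary reports mean/sd and a Wilcoxon signed-rank test
against zero (p = 1 when all deltas are exactly zero, where the statistic
is undefined). Transition matrices count baseline→follow-up moves over
{absent, stubby, stringy}, with transient plugs entering the absent
column and new plugs the absent row; the absent→absent cell is
structurally zero because unplugged airways are not enumerated.

## Association statistics

The resampling unit of the bootstrap is the patient: a replicate draws
patients with replacement and keeps all of a drawn patient's scans (with
multiplicity), respecting repeated measures. Confidence intervals are
percentile-based (2.5/97.5), matching the percentile wording of the
procedure being reproduced rather than BCa. The proximal-vs-distal
contrast is judged from the bootstrap distribution of
`r_s(proximal) − r_s(distal)`, reported as a one-sided tail probability
and a percentile interval. Replicates in which a resampled column is
constant have an undefined coefficient and are dropped from that group's
distribution with a count; a constant column in the full table is an
error. SHAP attributions use the exact linear-model identity
`φ_ij = β_j·(x_ij − x̄_j)` with the analyzed table itself as the
background (mean imputation); this equals brute-force Shapley enumeration
over feature subsets and satisfies local accuracy row by row, both
asserted in tests.

## Synthetic phantoms — what they emulate and what they do not

Trees are strictly bifurcating with per-generation length and radius
ratios (radius default `2^(−1/3)`, the area-preserving symmetric-lung
scaling; an 18 mm trachea then puts generations 6–9 at 2–4.5 mm diameter,
the calibre band where plugs concentrate). Branch angles are fixed with
seeded multiplicative jitter on lengths, radii and angles; lobes are
contiguous groups of the subtree roots at the shallowest generation with
at least `lobe_count` branches (generation 3 for five lobes — a strictly
bifurcating tree has only four depth-2 subtrees, so five lobes cannot be
assigned there — and generation 2 for four). Phantom HU defaults are
parenchyma −870 ± 40, lumen −1000, plug −150 ± 30: plausible contrast,
and the segmentation must be intensity-scale-free anyway. Plugs are
flat-ended cylinders coaxial with the branch at the full lumen radius
(total occlusion, the premise of RS and OLVP); lumens are capsules so
branch joints fill smoothly. Simulated readers draw the tightest
axis-aligned ellipse enclosing each slice cross-section (plus a half-voxel
margin) and then miss whole plugs, skip slices, and dilate extents with
zero-mean noise; dilation never shrinks a mark below a voxel-scale floor.
Follow-up simulation keeps each plug on its branch with the configured
persistence probability (default 0.47, the observed three-year
persistence fraction), jitters sizes with zero-mean Gaussians, and adds
new plugs on unplugged terminals at a Poisson rate.

Default study-scale conditions (reader miss 0.1 / skip 0.05 / dilation
0.5 voxels; follow-up persistence 0.47) are fixed once; the oracle
experiments use explicitly stated smaller trees and grids (≤ 6
generations, 28³–112³ voxel grids at 0.5–1 mm spacing) so each check runs
in seconds to minutes on one CPU.

Phantoms deliberately omit: lung texture and airway walls, partial-volume
effects, respiratory motion, inspiration/expiration pairing, reader false
positives, and anatomically labeled (Boyden) segments. Passing tests
therefore establish algorithmic correctness — geometry, scoring,
network solves, matching, statistics — not clinical segmentation accuracy
in the presence of wall artifacts or annotation ambiguity, which only
expert-annotated scans can establish.

## Numerical choices and degenerate inputs

Membership updates put all mass on a centroid-coincident point; GK input
with a single distinct intensity raises a degenerate-input error. The
resistance system is solved densely (trees here have ≤ a few hundred
branches); the inlet Dirichlet condition keeps it nonsingular whenever
any outlet is open, and `Q ≤ 0` is mapped to the infinite flag. Empty
plug masks are upstream failures and raise rather than propagate zero
volumes. Mixture fits skip k when the parameter count reaches the sample
size, with a notice. Bootstrap and EM seeds, tree seeds and phantom
seeds are all explicit; every generator is a pure function of its
configuration plus seed.
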