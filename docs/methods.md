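# Methods

This note documents the models and procedures implemented in
`guildspace`, the defaults chosen where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Shape analysis

**Superimposition.** Configurations are centred, scaled to unit
centroid size and rotated by least squares onto a running consensus
(reflections disallowed: mandibles are digitised in lateral view on one
side, so an improper rotation is never a valid match). The consensus is
re-estimated each pass and the loop stops when its RMS change falls
below `tol` (default 1e-7, past plotting precision) or after `max_iter`
(default 100) passes. The starting reference is the configuration with
the lexicographically smallest specimen id, which makes the whole
procedure invariant to input order.

**Sliding semilandmarks.** Each semilandmark may slide along the chord
spanned by its two immediate outline neighbours (fixed or sliding);
curve anchors never slide. The update moves the point along the chord
direction from its current position to the location minimising its
squared distance to the matching consensus landmark — a closed-form 1-D
projection, so the summed squared deviation from the reference never
increases. Because neighbours slide too, unlimited iteration lets
points creep along the outline indefinitely (the criterion keeps
improving by vanishing amounts while semilandmark spacing degrades);
sliding is therefore interleaved with re-alignment for a fixed number
of early passes (`slide_iterations`, default 5), after which plain
alignment continues to convergence. Sliding is always against the
current consensus, not a designated reference specimen.

**Shape variables.** Aligned coordinates are used directly; no
projection to tangent space. At the Procrustes distances typical of
within-sample jaw variation the chordal and geodesic metrics differ far
below the tolerances used anywhere downstream; this is an approximation
and is logged as such in the code.

**Pairwise distance.** `procrustes_distance` is the Euclidean norm of
the coordinate difference of two already-aligned configurations (the
quantity the disparity module consumes). `opa_distance` superimposes a
raw pair from scratch, optionally with the analytic least-squares scale,
giving the full Procrustes distance used in oracle tests.

## Functional characters

Seven ratios and one angle, computed from ten linear measurements:
MA_ant = closing in-lever / anterior out-lever, MA_post = closing
in-lever / posterior out-lever, MA_open = opening in-lever / anterior
out-lever, MAR = maximum depth / jaw length, RSL = symphysis length /
jaw length, AO = perpendicular articulation offset / jaw length, RTL =
tooth-row (or functional-surface) length / jaw length, and SA in
degrees. A single closing in-lever serves both MA variants (the
out-lever varies with bite point); for edentulous taxa RTL uses the
length of the mandibular functional surface, resolved in the
measurement table rather than in code. SA stays in degrees: its only
downstream consumer is the z-transform, which is unit-consistent.
Missing measurements exclude a taxon listwise with a logged report; a
non-positive denominator is an error naming taxon and character.

The standardised table (SFMD) is the column z-score with sample (n−1)
SDs; the means and SDs are retained so the transform can be inverted or
applied to new taxa. All characters are invariant to global rescaling
of the raw lengths, and SFMD Euclidean distances are invariant to
affine re-expression of any raw column.

## Ordination

Shape PCA is a covariance PCA of the aligned coordinates (centred
only); functional PCA operates on the pre-z-scored SFMD, equivalent to
a correlation PCA of the raw characters. Both use an SVD; variance
fractions are eigenvalue shares over all non-null axes and sum to one.
Eigenvector signs are fixed by making each axis' largest-magnitude
loading positive, so plots and CSVs are reproducible. Character
contributions to an axis are 100·loading²/Σloading². Functional
characters are painted over shape morphospace by piecewise-linear
interpolation on a Delaunay triangulation of the (PC1, PC2) scores,
default 200×200 grid over the occupied bounding box; nodes outside the
convex hull are reported missing rather than extrapolated.

## Guild clustering

The Euclidean distance structure of the SFMD is clustered three ways:
Ward agglomerative (the named toolchain's default linkage; configurable),
best-of-n-starts Lloyd K-means, and PAM with greedy BUILD and
steepest-descent SWAP (authored here; deterministic for a given
matrix). The number of clusters is selected from a configured range —
default 4–10 for the top level — by the gap statistic: B reference data
sets drawn uniformly in the principal-axis-aligned bounding box,
Gap(k) = E*[log W_k] − log W_k with W_k the within-cluster sum of
squares, s_k = sd·√(1+1/B), and the 1-SE rule (smallest k with
Gap(k) ≥ Gap(k+1) − s_{k+1}), falling back to the arg-max when the rule
never fires. B defaults to 2000; tests and the acceptance script use
B=100, which the recovery experiments show is ample at study scale.

Consensus: the K-means and PAM labels are matched to the hierarchical
labels by greedy maximum overlap on the contingency table (Hungarian
assignment available behind a flag); taxa on which all three matched
labelings agree form the core guilds, the rest are flagged inconsistent
and, for reporting, attached to the guild of their nearest core taxon
in SFMD space — the flag is retained, and inconsistent taxa remain in
all disparity computations (disparity is guild-agnostic). Guild names
are assigned to core clusters in decreasing size order from the
five-name FFG vocabulary (ingestion generalist, prehension specialist,
durophagous specialist, shearing pulper, heavy oral processor).

Sub-clustering re-runs the entire pipeline inside one guild and writes
FFsG labels (basal generalist, tough generalist, light oral processor)
for that guild's taxa only. Its k-range defaults to 2–6 rather than
4–10: a three-subgroup outcome must be expressible, and a subset of a
few dozen taxa cannot support ten clusters.

Validation: silhouette widths from the distance matrix (singletons
score 0), and external comparison against taxonomic labelings via the
adjusted Rand index and variation of information (entropy sum minus
twice the mutual information, in nats). Clades are mapped to guilds by
the plurality of their consistent taxa; ties are reported as
"unresolved", never broken silently.

## Disparity through time

Taxa enter every bin between their first and last appearance
(range-through; occurrence-only binning is available behind a flag).
The default bin table spans Changhsingian–Toarcian at stage level with
lower/upper Carnian and lower/middle/upper Norian splits, with ages
from the 2019 international chronostratigraphic chart; it is a config
table and fully overridable.

Three disparity metrics are reported side by side: mean pairwise
distance (MPD) with a bootstrap percentile 95% CI (taxa are resampled
with replacement; pairs drawing the same original taxon twice are
excluded from the resampled mean), the trace of the sample covariance
(sum of variances, n−1), and Procrustes variance (mean squared distance
to the member mean, 1/n). Bins with fewer than two members yield
missing estimates. Bootstrap default is 1000 cycles.

NPMANOVA partitions the squared-distance matrix into among- and
within-group sums of squares (Gower), forms
pseudo-F = (SS_A/(g−1))/(SS_W/(n−g)), and estimates p by the add-one
permutation estimator over random label permutations (default 9999;
pairwise mode multiplies p by the number of tests actually run, capped
at 1, and skips pairs with a group below two members). The pseudo-F
agrees exactly with the independent PERMANOVA implementation in
scikit-bio on test fixtures. Note that in a saturated two-group case
the smallest achievable p can be 2/(P+1) rather than 1/(P+1) whenever
the random permutations happen to include the full label swap, which
reproduces the observed partition. Note also that duplicating every
observation preserves the among/within sum-of-squares ratio but not
pseudo-F itself, whose degrees of freedom change with n.

Morphospace time slices are convex hulls (vertices and area) per clade
per bin on PC1–PC2; fewer than three or collinear points give a
degenerate hull of area zero. Clade divergence is the per-bin Euclidean
distance between clade mean vectors, computed in both shape and
function space.

## Assemblages

Relative richness by clade and relative abundance by diet class per
locality, with specimen counts as weights when complete and a logged
equal-weight downgrade otherwise. A "trophic conflict" is an unordered
pair of co-occurring herbivores sharing a guild label; pair counting is
primary and the number of conflicted taxa is emitted alongside, since
either reading of a "conflict count" is defensible. At FFsG resolution
a taxon's label is its subgroup when one exists and its FFG otherwise,
so refinement can never increase the count. Herbivores outside the
morphometric sample may inherit their clade's majority guild; taxa that
still lack a label are excluded with a log entry.

## Synthetic data

The generator emulates the study's structure without reusing any of its
data or algorithms: guild centres are drawn in z-score space and scaled
so their minimum pairwise separation equals the configured value in
within-guild SD units (members are isotropic Gaussians); each clade has
a home guild joined with probability `fidelity`; an optional second
layer plants subgroups inside guild 1. Characters are emitted on
plausible raw scales (e.g. anterior MA ≈ 0.28 ± 0.05, SA ≈ 35° ± 8°)
and can be back-solved into a positive-length measurement table so the
ratio stage is exercised end to end (infeasible draws are resampled).
Shapes are deformations of a 59-point mandible-like template (4 fixed
anchors, 4 curves of 13–15 semilandmarks) by per-group low-order
trigonometric radial displacement fields — deliberately not thin-plate
splines, to keep the generator independent of the analysis code — plus
iid landmark noise and random similarity transforms. Ranges draw
first-appearance bins uniformly with geometric durations; assemblages
sample co-occurring taxa with log-normal abundance counts, optionally
forcing a fixed number of same-guild pairs into one locality.

Defaults are the study-scale conditions: 136 taxa, 5 guilds, 8
characters, 59 landmarks, separation 6, within-guild SD 1, 10 clades at
fidelity 0.9, bins Changhsingian–Toarcian. The generator does **not**
emulate phylogenetic autocorrelation of characters, non-isotropic or
heavy-tailed within-guild variation, missing-data patterns, or
preservation/sampling biases in the fossil record — so passing recovery
tests demonstrate correctness of the machinery under the stated
statistical conditions, not robustness to everything real jaw data can
do. The two-group shape generator at its default deformation-to-noise
ratio yields a far more dominant PC1 than real mandible samples show;
it is built to test separation and invariances, not to mimic realistic
eigenvalue spectra.

## Problem sizes and numerical choices

Recovery experiments run at the full study scale (136 taxa); the gap
statistic uses B=100 reference sets in tests and the acceptance script,
the NPMANOVA calibration uses 1000 null data sets of n=30 with 999
permutations, and disparity bootstraps use 100–10000 cycles depending
on the check — sizes at which every experiment completes in seconds to
a few minutes on one core. Convergence tolerances: GPA consensus RMS
1e-7; PAM swap improvement threshold 1e-12; PCA rank cut at 1e-12
relative to the leading singular value. Degenerate inputs (zero-size
configurations, zero-length chords, zero-variance characters,
all-identical points, single-member groups) raise named errors or are
skipped with log entries as documented per function, never silently
coerced.

## Known limitations

- Sliding uses the chord (secant) geometry only; minimum-bending-energy
  sliding is out of scope.
- No tangent-space projection (see above) and no phylogenetic
  correction anywhere in the pipeline.
- The consensus rule (greedy contingency matching + unanimity) is one
  defensible operationalisation of "consensus across methods"; near-miss
  taxa are handled by the inconsistent flag plus nearest-core
  attachment rather than by any fuzzy membership.
- The alternative data-standardisation variant of the functional
  analysis is exposed only as a configuration hook (the z-transform is
  pluggable), not implemented speculatively.
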