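# Methods

This note documents the statistical machinery, the synthetic study design,
and the numerical choices behind `phylodisp`. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` compute.

## Dispersion metrics and the taxa-shuffle null

For a community with abundances *n&#7522;* over species whose pairwise
distances are *d&#7522;&#11388;* (patristic distances on the phylogeny, or
cophenetic distances on a trait dendrogram — the code is identical for
both):

* MPD = Σ<sub>i≠j</sub> n&#7522;n&#11388;d&#7522;&#11388; /
  Σ<sub>i≠j</sub> n&#7522;n&#11388;
* MNTD = Σ&#7522; n&#7522; · min<sub>j≠i</sub> d&#7522;&#11388; / Σ&#7522; n&#7522;

"Between all individuals" is ambiguous about conspecific pairs, whose
distance is zero. We exclude them: including them deflates MPD mechanically
as abundance concentrates, conflating evenness with relatedness; excluding
them is the dominant convention for abundance-weighted MPD/MNTD. This is a
documented decision, not a derived fact, and the CLI help repeats it.

The null model randomizes species *names* on the distance matrix: each
replicate maps the community's observed abundance vector onto a uniformly
random richness-sized subset of the pool. Richness and the abundance
multiset are preserved exactly; nothing else is constrained
(independent-swap style nulls are out of scope). SES = (obs − null mean)/
null SD over 999 replicates by default; the rank 1 + #{null < obs} gives a
one-sided quantile. Null draws are seeded per (cell, metric, basis) from a
master seed, so results are independent of evaluation order and stable
under any parallelization.

Degenerate cases: cells with fewer than two species get all-NaN rows (and
are dropped listwise before any regression); a null SD within 1e-12 of zero
relative to the metric's magnitude (e.g. the whole pool at equal abundance,
which is invariant under relabeling) flags the SES as undefined rather than
dividing by float noise.

## Blomberg's K

With C the shared branch-length matrix (C&#7522;&#11388; = root-to-MRCA path
length; computed as (depth&#7522; + depth&#11388; − d&#7522;&#11388;)/2 from
the cophenetic matrix, which is also how community submatrices are obtained
without re-pruning),

* â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1)
* K = [ (x−â)ᵀ(x−â) / (x−â)ᵀC⁻¹(x−â) ] / [ (tr C − n/(1ᵀC⁻¹1)) / (n−1) ]

K = 1 is the Brownian-motion expectation; the star phylogeny gives K = 1
identically for any trait, which the tests assert to 1e-10 together with
invariance to trait affine maps and global branch rescaling. C is factorized
once per tree (Cholesky, with a 1e-10·tr(C)/n diagonal jitter retry for
near-singular polytomy-rich trees) and reused across the 999 trait-shuffle
permutations, which are evaluated as one vectorized batch. The permutation
p-value uses the add-one rule, so it is never exactly zero. Community-level
K requires at least `min_taxa = 4` species (configurable); K on three tips
is numerically legal but statistically vacuous. K is species-level;
abundances only determine presence. The clustered/overdispersed comparison
uses Welch's unequal-variance t-test on defined K values, grouping cells by
the sign of SES.MPD (exact zeros belong to neither group).

## Trait space

Traits are optionally log-transformed (natural log; the base only rescales
z-scores) and z-scored with the sample SD. Species with any missing trait
are dropped with a warning. PCA retains the smallest number of components
reaching the cumulative explained-variance target (default 0.90), with an
`n_components` override to mimic fixed-count choices; rank-deficient tables
retain at most their rank. Dendrograms use Euclidean distances between
species score rows and average linkage (UPGMA) — the linkage is not dictated
by the problem, but UPGMA yields ultrametric cophenetic distances,
symmetric with the phylogeny; complete/single linkage are available flags.
Cophenetic distance is the merge height, so duplicated species rows merge at
zero. SES on a dendrogram is invariant to any monotone rescaling of the
underlying trait because standardization precedes clustering.

## dbMEM and environmental predictors

Cell centres give a Euclidean distance matrix D; the truncation threshold t
defaults to the longest minimum-spanning-tree edge (the cell spacing on a
full regular grid); entries above t are replaced by 4t; PCoA
(eigen-decomposition of −½·J(D*∘D*)J) yields eigenvectors scaled by
√eigenvalue, and only eigenvalues above 1e-8 of the largest are kept —
positive spatial autocorrelation only, broadest scales first. Cells are
ordered row-major from the plot origin so the basis is bit-reproducible.
On regular grids the spectrum has ties, so individual eigenvectors are
defined only up to rotation within an eigenspace; comparisons against
classical PCoA are therefore made on the rotation-invariant score Gram
matrix.

Environmental expansion: every non-aspect variable is centred, raised to
powers 1–3 (powers of the *centred* variable, limiting collinearity), each
column re-centred; aspect (degrees) enters as sin and cos. Thirteen
non-aspect variables + aspect give 41 columns. Constant variables would
expand to all-zero columns and are dropped with a warning. For scales
coarser than the native environmental grid, cell values are averaged
(aspect circularly, via its sine and cosine); for finer scales each cell
inherits its parent's values.

## Forward selection and variation partitioning

The response (one SES column) is univariate, so redundancy analysis reduces
exactly to OLS; all permutation schemes are the standard ones. A global
permutation F-test (free permutation of y) gates selection: a nonsignificant
candidate pool selects nothing. Each step adds the candidate with the
largest incremental R² (computed by projecting candidates onto the orthogonal
complement of the selected set, so a step is one vectorized pass) and tests
it by permuting the reduced-model residuals; selection stops when that p
exceeds α, or — the double stopping rule — once the selected set's adjusted
R² reaches the full candidate model's (the significant variable that crosses
the ceiling is kept; later ones are not considered). When the candidate
space has rank ≥ n−1 the ceiling uses the n−2 leading axes, with a warning.

Partitioning of y against X1 (selected env/space) and X2 (phylogenetic
dispersion) uses Ezekiel-adjusted R²: a = adjR2(X1∪X2) − adjR2(X2),
c = adjR2(X1∪X2) − adjR2(X1), b = adjR2(X1)+adjR2(X2)−adjR2(X1∪X2),
d = 1 − adjR2(X1∪X2); the additivity identities hold to 1e-12 and fractions
may be slightly negative (an accepted artefact of the adjustment). The pure
X2 fraction is tested by permuting residuals of y ~ X1 and comparing the
partial F of X2 | X1 with its permutation distribution. The pipeline
reports three rows per (scale, size class, metric): "Phylo" (marginal
adjR2 of X2), "−S" (pure X2 after space-only selection) and "−ES" (pure X2
after joint environment+space selection — selection is joint by default,
with a flag for separate selection). When the marginal y ~ X2 relationship
is itself nonsignificant, all three rows are reported NA: a partition of a
nonexistent relationship is not interpretable. Defaults: α = 0.05,
9,999 permutations for publication-grade runs (the pipeline and tests use
smaller counts, stated per run in the manifest, purely to keep iteration
fast).

## The synthetic study design

The generator emulates a stem-mapped temperate forest plot at desk scale:
a 300 m × 300 m plot, a 40-species pool on a depth-100 Yule tree, 20,000
stems with dbh ≥ 1 cm, 20-m environmental cells, and three dbh size classes
(≤5, 5–10, >10 cm) of canopy species (max dbh > 10 cm). Species maximum dbh
is lognormal (median 15 cm, σ = 0.7, so roughly two-thirds of species are
canopy); stem dbh is truncated-exponential within [1 cm, species max].

*Trees* are pure-birth (Yule) with all tip depths rescaled to the target
age; a birth–death generator would add nothing the downstream tests need.
*Traits* follow the λ-transform family: Brownian motion (λ = 1) through a
star covariance (λ = 0), plus tip-shuffled Brownian draws that destroy
signal while preserving the marginal distribution. The default pool has
eight traits spanning that gradient (three Brownian, λ = 0.7/0.4/0.2, two
shuffled), the spread real trait surveys report. *Environment* is a
low-order polynomial trend plus moving-average-smoothed Gaussian noise,
giving positive, distance-decaying spatial autocorrelation; aspect is a
smooth direction field.

*Assembly.* Filtering gives each species an environmental optimum by
linearly mapping the filter trait onto the observed range of the filter
variable; a stem lands in a cell with probability ∝ exp(−(env −
optimum)²/2σ²) with σ = 10% of the environmental range (strong filtering —
the regime the scenario exists to represent). Limiting similarity places
stems sequentially and rejects a candidate cell if any resident is within
r_s = 1.0 trait SD of the candidate in the similarity trait; conspecifics
are trivially within the radius, so each cell saturates near its
trait-spaced capacity — the preset therefore uses 900 stems (~4 per 20-m
cell), and after 50 failed cells a stem is placed anyway and counted in
`attrs["n_fallback"]`. Neutral assembly draws species uniformly and cells
uniformly; with uniform species frequencies the taxa-shuffle null coincides
exactly with the generative sampling conditional on cell abundances, which
is what makes the SES calibration check meaningful (a lognormal abundance
option exists for realism, but skewed pools bias presence toward common
species and are a known source of SES miscalibration, so they are not the
calibration default).

*Conditioning on the conserved premise.* The mechanism scenarios are
defined by filtering or spacing on a trait that *is* conserved. A single
Brownian draw on a ~40-tip tree is wildly variable in realized signal
(realized K well below 1 is common), and the congruence between a trait
set's distances and the tree is further capped by the tree realization
itself. Empirical studies do not face this ambiguity: they measure each
trait's K and select high-signal traits before relying on them. The
generator mirrors that practice deterministically: Brownian traits are
redrawn (from substreams of the seed) until realized K ≥ 1, and the system
(tree + trait table) is redrawn until the standardized trait-space distances
correlate with cophenetic distances at ≥ 0.6. Both floors are configurable
and can be disabled (`conserved_k_min=None`, `trait_tree_corr_min=None`)
for raw draws; the trait-simulation operation itself is never conditioned,
and its Brownian calibration (mean K ≈ 1) is asserted on raw draws.

*What the generator does not emulate:* realistic demography and dispersal
kernels, intraspecific trait variation, measurement error, and soil
variables interpolated from off-grid samples. Passing tests therefore show
the machinery is correct and the mechanisms are recoverable under the
stated conditions — not that any particular real forest behaves this way.

## Problem sizes and calibration checks

The neutral SES calibration pools cells from three replicate plots
(3 × 225 = 675 cells at the 20-m scale, 999 nulls) so the across-cell mean
and SD are estimated at the ~500-cell scale the check is designed for.
Monte-Carlo calibrations use 500 replicates with 199 permutations where a
rejection *rate* is the quantity of interest; mechanism-recovery scenarios
use the full 999-null SES. The end-to-end pipeline checks use a reduced
grid (one to two scales, 49–199 nulls) because they assert structure and
determinism, not power.

## Known limitations

* The null model is the taxa shuffle only; frequency- or richness-
  constrained swap nulls are deliberately out of scope.
* Gower distances and categorical traits are unsupported; trait dendrograms
  assume real-valued, standardizable traits.
* Negative-eigenvalue MEMs (negative spatial autocorrelation) are not
  returned.
* Multivariate-response RDA (several SES columns at once) is not
  implemented; each response is partitioned separately.
* Blomberg's K at the community level is undefined below four taxa, so very
  sparse cells contribute nothing to the signal comparison.
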