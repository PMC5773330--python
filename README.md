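# phylodisp

Phylogenetic and trait dispersion of mapped forest communities — and how far
one predicts the other.

Community ecologists often use the relatedness of co-occurring species as a
proxy for their functional similarity: if close relatives share traits, a
plot whose species are phylogenetically clustered should also be clustered
in trait space. `phylodisp` implements the full analysis chain needed to
test that proxy on a stem-mapped forest plot, and a synthetic-data generator
that builds plots with *known* assembly mechanism so every stage can be
validated against ground truth.

## What it computes

**Dispersion.** For each grid cell (10/20/30/50-m scales; small/medium/large
dbh classes of canopy species, or all stems) the abundance-weighted mean
pairwise distance (MPD) and mean nearest-taxon distance (MNTD) over either
the phylogeny's patristic distances or a trait dendrogram, standardized
against 999 taxa-shuffle null communities:

    SES.MPD = (MPD_obs − mean(MPD_null)) / SD(MPD_null)

Negative SES = clustering, positive = overdispersion. Conspecific (zero)
distances are excluded; the null maps each community's abundance vector onto
a uniformly random subset of the pool, preserving richness and abundances.

**Phylogenetic signal.** Blomberg's K with a 999-permutation trait-shuffle
test, at the species-pool level and on the pruned subtree of every cell's
community, plus a Welch t-test comparing K between phylogenetically
clustered and overdispersed cells (split by the sign of SES.MPD).

**Trait space.** Log/z-scored trait tables, PCA reduction to a cumulative
explained-variance target, and UPGMA dendrograms whose ultrametric
cophenetic distances plug straight into the dispersion machinery.

**Space and environment.** Distance-based Moran's eigenvector maps (dbMEM:
truncated inter-cell distances, distances beyond the threshold t replaced by
4t, PCoA, positive eigenvectors only) and third-degree polynomial expansion
of the environmental variables plus sin/cos(aspect) — 13 raw variables + aspect
→ 41 predictors.

**Variation partitioning.** Forward selection of env/space predictors
(permutation F tests with the double stopping rule, global-test gate), then
adjusted-R² partitioning of trait dispersion into pure-phylogenetic, shared,
and env/space fractions, with a residual-permutation test of the pure
phylogenetic fraction. Reported as the marginal "Phylo" fit and the pure
fractions after space-only ("−S") or environment+space ("−ES") control.

**Synthetic data.** Yule trees; traits evolved as Brownian motion, Pagel's
λ-transforms, or tip-shuffled draws; autocorrelated environmental surfaces;
and ~20,000-stem plots assembled by environmental filtering, limiting
similarity, or neutral placement — all byte-reproducible from one seed.

## Worked example

`examples/01_dispersion_basics.py` builds a 12-species pool and one
five-species community:

```
observed MPD  =   175.74 My
observed MNTD =   124.67 My
SES.MPD : obs= 175.74  null= 141.61 +- 28.37  SES=+1.20  rank=978/1000
SES.MNTD: obs= 124.67  null=  64.45 +- 31.43  SES=+1.92  rank=954/1000
```

Both metrics sit above their null means (positive SES): this community is
phylogenetically overdispersed — its species are *less* related than a
random pool draw — though at rank 978/1000 the MPD excess is not extreme.

`examples/04_space_environment_varpart.py` runs the control analysis on a
filtering scenario at the 20-m scale:

```
dbMEM: 156 positive eigenvectors (truncation 20 m)
environment: 41 polynomial/aspect predictor columns
forward selection kept 22 of 197 candidates: ['elevation^2', 'elevation^3', ...]

adjR2: env+space=0.495  phylo=0.807  joint=0.846
fractions: pure env/space a=0.039  shared b=0.456  pure phylo c=0.351  residual d=0.154
pure-phylogeny permutation test: p = 0.001
```

Phylogenetic dispersion alone explains 81% of the variance in trait
dispersion; about half of that is shared with the spatially structured
environment (the filtering mechanism is itself environmental), but a pure
phylogenetic fraction of 0.35 survives the control and is significant.

The other examples cover scenario generation (`02`), pool- versus
community-level signal (`03`), and the full design grid with CSV outputs
(`05`). The `phylodisp` console script exposes the same pipeline as
`simulate`, `run`, `ses`, `signal` and `partition` subcommands.

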