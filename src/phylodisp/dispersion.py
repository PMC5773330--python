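"""Community dispersion: MPD, MNTD, the taxa-shuffle null, and SES.

The standardized effect size of a community's mean pairwise distance (MPD)
or mean nearest-taxon distance (MNTD),

    SES = (obs - mean(null)) / SD(null),

is computed against a null of randomizing species names on the pool distance
matrix: each null replicate maps the community's observed species (with their
abundances) onto a uniformly random subset of the pool, preserving richness
and the abundance vector.  Negative SES means the co-occurring taxa are
closer than chance (clustering); positive means overdispersion.  The distance
matrix may come from the phylogeny or from a trait dendrogram — the machinery
is identical.

Both metrics are abundance-weighted over interspecific pairs only:
conspecific pairs (distance zero) are excluded, so MPD =
sum_{i != j} n_i n_j d_ij / sum_{i != j} n_i n_j and MNTD weights each
species' nearest interspecific neighbour by its abundance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree_ops import DistanceMatrix

__all__ = [
    "GridSpec",
    "CommunityTable",
    "SESResult",
    "build_communities",
    "mpd",
    "mntd",
    "ses",
    "ses_table",
    "classify_pattern",
]

SIZE_CLASSES = ("small", "medium", "large", "all")
CANOPY_DBH = 10.0   # cm; species whose max dbh exceeds this are canopy species
_METRIC_CODE = {"mpd": 0, "mntd": 1}


@dataclass(frozen=True)
class GridSpec:
    """Square grid over a square plot; cells are half-open [k*s, (k+1)*s)."""

    plot_size: float
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        k = self.plot_size / self.cell_size
        if abs(k - round(k)) > 1e-9:
            raise ValueError("cell size must divide plot size exactly")

    @property
    def n_side(self) -> int:
        return int(round(self.plot_size / self.cell_size))

    @property
    def n_cells(self) -> int:
        return self.n_side ** 2

    def cell_ids(self) -> list[str]:
        n = self.n_side
        return [f"{i}_{j}" for i in range(n) for j in range(n)]

    def cell_centers(self) -> np.ndarray:
        n, s = self.n_side, self.cell_size
        ox, oy = self.origin
        out = np.empty((n * n, 2))
        r = 0
        for i in range(n):
            for j in range(n):
                out[r] = (ox + (j + 0.5) * s, oy + (i + 0.5) * s)
                r += 1
        return out


@dataclass
class CommunityTable:
    """Cells x species abundance matrix at one (scale, size class)."""

    grid: GridSpec
    size_class: str
    matrix: pd.DataFrame   # index: cell_id row-major; columns: species

    @property
    def n_cells(self) -> int:
        return len(self.matrix)

    def richness(self) -> pd.Series:
        return (self.matrix > 0).sum(axis=1)


def build_communities(stems: pd.DataFrame, cell_size: float,
                      size_class: str = "all", plot_size: float = 300.0,
                      canopy_dbh: float = CANOPY_DBH) -> CommunityTable:
    """Aggregate a stem table into a cells x species abundance matrix.

    Cell index is (floor(y/s), floor(x/s)) with half-open cells.  The three
    dbh size classes (small <= 5 cm, medium 5-10 cm, large > 10 cm) are
    restricted to canopy species — species whose maximum observed dbh across
    the whole stem table exceeds `canopy_dbh` — while ``"all"`` keeps every
    stem of every species.
    """
    if size_class not in SIZE_CLASSES:
        raise ValueError(f"unknown size class {size_class!r}")
    x = stems["x"].to_numpy(float)
    y = stems["y"].to_numpy(float)
    if (x < 0).any() or (y < 0).any() or (x >= plot_size).any() or (y >= plot_size).any():
        raise ValueError("stem coordinates outside the plot")
    grid = GridSpec(plot_size, cell_size)

    sel = np.ones(len(stems), dtype=bool)
    if size_class != "all":
        dbh = stems["dbh"].to_numpy(float)
        if size_class == "small":
            sel = dbh <= 5.0
        elif size_class == "medium":
            sel = (dbh > 5.0) & (dbh <= 10.0)
        else:
            sel = dbh > 10.0
        max_dbh = stems.groupby("species")["dbh"].max()
        canopy = set(max_dbh.index[max_dbh > canopy_dbh])
        sel &= stems["species"].isin(canopy).to_numpy()

    n = grid.n_side
    ci = (np.floor(y / cell_size).astype(int) * n
          + np.floor(x / cell_size).astype(int))
    sub = pd.DataFrame({"cell": ci[sel], "species": stems["species"].to_numpy()[sel]})
    counts = sub.groupby(["cell", "species"]).size().unstack(fill_value=0)
    species_cols = sorted(stems["species"].unique())
    mat = pd.DataFrame(0, index=np.arange(grid.n_cells), columns=species_cols,
                       dtype=int)
    mat.loc[counts.index, counts.columns] = counts
    mat.index = pd.Index(grid.cell_ids(), name="cell_id")
    return CommunityTable(grid, size_class, mat)


# ---------------------------------------------------------------------------
# metrics

def _abund_vector(abund, dist: DistanceMatrix):
    if isinstance(abund, pd.Series):
        abund = abund[abund > 0]
        labels = list(abund.index)
        n = abund.to_numpy(float)
    else:
        items = [(k, v) for k, v in dict(abund).items() if v > 0]
        labels = [k for k, _ in items]
        n = np.array([v for _, v in items], float)
    if len(labels) < 2:
        raise ValueError("need at least 2 species with positive abundance")
    ix = dist.indexer(labels)
    return n, dist.values[np.ix_(ix, ix)]


def _mpd_from(n: np.ndarray, d: np.ndarray) -> float:
    w = np.outer(n, n)
    np.fill_diagonal(w, 0.0)
    return float((w * d).sum() / w.sum())


def _mntd_from(n: np.ndarray, d: np.ndarray) -> float:
    dd = d + np.diag(np.full(len(n), np.inf))
    return float((n * dd.min(axis=1)).sum() / n.sum())


def mpd(abund, dist: DistanceMatrix) -> float:
    """Abundance-weighted mean pairwise interspecific distance."""
    n, d = _abund_vector(abund, dist)
    return _mpd_from(n, d)


def mntd(abund, dist: DistanceMatrix) -> float:
    """Abundance-weighted mean distance to the nearest other species."""
    n, d = _abund_vector(abund, dist)
    return _mntd_from(n, d)


# ---------------------------------------------------------------------------
# SES

@dataclass(frozen=True)
class SESResult:
    cell_id: str | None
    metric: str
    basis: str
    obs: float
    null_mean: float
    null_sd: float
    ses: float
    rank: int
    n_null: int

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.ses)


def ses(abund, dist: DistanceMatrix, metric: str = "mpd", n_null: int = 999,
        seed: int = 0, *, rng: np.random.Generator | None = None,
        basis: str = "phylogeny", cell_id: str | None = None) -> SESResult:
    """Standardized effect size of MPD or MNTD under the taxa-shuffle null.

    Each of the `n_null` replicates assigns the community's abundance vector
    to a uniformly random subset of the pool taxa (sampling labels without
    replacement from the distance matrix).  `rank` is 1 + the number of null
    values strictly below the observation, so rank/(n_null + 1) is a one-sided
    quantile.  If the null SD is zero (e.g. the community equals the whole
    pool of an equidistant matrix) the SES is NaN and flagged undefined.
    """
    if metric not in _METRIC_CODE:
        raise ValueError(f"unknown metric {metric!r}")
    stat = _mpd_from if metric == "mpd" else _mntd_from
    n, d = _abund_vector(abund, dist)
    obs = stat(n, d)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    k, pool = len(n), dist.n
    nulls = np.empty(n_null)
    D = dist.values
    for r in range(n_null):
        ix = rng.choice(pool, size=k, replace=False)
        nulls[r] = stat(n, D[np.ix_(ix, ix)])
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd <= 1e-12 * max(abs(mu), abs(obs)):    # degenerate null (all equal)
        sd = 0.0
    z = (obs - mu) / sd if sd > 0 else float("nan")
    rank = int(1 + (nulls < obs).sum())
    return SESResult(cell_id, metric, basis, obs, mu, sd, z, rank, n_null)


def ses_table(comm: CommunityTable, dist: DistanceMatrix, metric: str = "mpd",
              n_null: int = 999, seed: int = 0,
              basis: str = "phylogeny") -> pd.DataFrame:
    """Per-cell SES for one metric and basis.

    Cells with fewer than two species present are recorded with NaN
    statistics rather than raised.  Randomization is seeded per (cell,
    metric, basis) from the master seed, so results do not depend on cell
    evaluation order.
    """
    rows = []
    basis_code = zlib.crc32(basis.encode()) % (2 ** 20)
    for i, (cell_id, row) in enumerate(comm.matrix.iterrows()):
        present = row[row > 0]
        if (present > 0).sum() < 2:
            rows.append((cell_id, metric, basis, np.nan, np.nan, np.nan,
                         np.nan, 0, n_null, int((present > 0).sum())))
            continue
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(seed), i, _METRIC_CODE[metric], basis_code]))
        r = ses(present, dist, metric, n_null, rng=rng, basis=basis,
                cell_id=cell_id)
        rows.append((cell_id, metric, basis, r.obs, r.null_mean, r.null_sd,
                     r.ses, r.rank, n_null, int((present > 0).sum())))
    return pd.DataFrame(rows, columns=[
        "cell_id", "metric", "basis", "obs", "null_mean", "null_sd", "ses",
        "rank", "n_null", "richness"]).set_index("cell_id")


def classify_pattern(ses_value: float) -> str | None:
    """Sign of SES.MPD: negative = clustered, positive = overdispersed.

    Exactly zero (or undefined) SES belongs to neither group and returns
    None; callers drop such cells from group comparisons.
    """
    if not np.isfinite(ses_value) or ses_value == 0.0:
        return None
    return "clustered" if ses_value < 0 else "overdispersed"
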