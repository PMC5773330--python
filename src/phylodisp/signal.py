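"""Blomberg's K phylogenetic signal, with permutation tests.

K compares the observed trait variance among tips (after removing the
phylogenetically weighted ancestral mean) with the variance expected if the
trait had evolved by Brownian motion along the tree.  With C the shared
branch-length (Brownian covariance) matrix,

    a_hat = (1' C^-1 x) / (1' C^-1 1)
    K = [ (x - a_hat)'(x - a_hat) / (x - a_hat)' C^-1 (x - a_hat) ]
        / [ (tr C - n / (1' C^-1 1)) / (n - 1) ]

K = 1 matches the Brownian expectation, K > 1 indicates stronger conservatism,
K < 1 a more labile trait.  Significance comes from shuffling trait values
across tips: p = (1 + #{K_perm >= K_obs}) / (1 + n_perm).

Community-level signal re-evaluates K on the species actually present in a
grid cell.  Pruning the pool tree to those species leaves their shared branch
lengths unchanged, so K is computed from the corresponding submatrix of the
pool's C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .dispersion import CommunityTable
from .tree_ops import Phylogeny

__all__ = [
    "SignalResult",
    "blomberg_k",
    "k_test",
    "community_signal",
    "compare_signal_by_pattern",
]


def _prep_C(C: np.ndarray):
    """Factor C once; returns pieces reused across permutations."""
    n = C.shape[0]
    jitter = 0.0
    for attempt in range(2):
        try:
            cho = linalg.cho_factor(C + jitter * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError:
            if attempt:
                raise
            jitter = 1e-10 * np.trace(C) / n
    Cinv = linalg.cho_solve(cho, np.eye(n))
    ones = np.ones(n)
    cinv1 = Cinv @ ones
    s11 = float(ones @ cinv1)
    expected = (np.trace(C) - n / s11) / (n - 1)
    return Cinv, cinv1, s11, expected


def _k_given(x: np.ndarray, Cinv, cinv1, s11, expected) -> float:
    a = float(cinv1 @ x) / s11
    r = x - a
    num = float(r @ r)
    den = float(r @ Cinv @ r)
    return (num / den) / expected


def _trait_vector(tree: Phylogeny, x) -> tuple[np.ndarray, np.ndarray]:
    C, labels = tree.shared_path_matrix()
    if isinstance(x, pd.Series):
        missing = set(labels) - set(x.index)
        if missing:
            raise ValueError(f"trait missing for tips: {sorted(missing)}")
        vec = x.reindex(list(labels)).to_numpy(float)
    else:
        vec = np.asarray(x, float)
        if len(vec) != len(labels):
            raise ValueError("trait vector length does not match tip count")
    return C, vec


def _validate(vec: np.ndarray):
    if len(vec) < 3:
        raise ValueError("Blomberg's K needs at least 3 taxa")
    if np.var(vec) == 0:
        raise ValueError("trait has zero variance")
    if not np.all(np.isfinite(vec)):
        raise ValueError("trait contains non-finite values")


def blomberg_k(tree: Phylogeny, x) -> float:
    """Blomberg's K of trait `x` (Series indexed by tip label, or array in
    sorted-tip order) on `tree`."""
    C, vec = _trait_vector(tree, x)
    _validate(vec)
    return _k_given(vec, *_prep_C(C))


@dataclass(frozen=True)
class SignalResult:
    trait: str
    level: str                  # "pool" or "community"
    cell_id: str | None
    n_taxa: int
    K: float
    p: float
    n_perm: int


def _k_test_core(C: np.ndarray, vec: np.ndarray, n_perm: int,
                 rng: np.random.Generator) -> tuple[float, float]:
    Cinv, cinv1, s11, expected = _prep_C(C)
    k_obs = _k_given(vec, Cinv, cinv1, s11, expected)
    n = len(vec)
    # vectorized permutations: rows of P are shuffled trait vectors
    P = np.empty((n_perm, n))
    for r in range(n_perm):
        P[r] = vec[rng.permutation(n)]
    a = (P @ cinv1) / s11
    R = P - a[:, None]
    num = np.einsum("ij,ij->i", R, R)
    den = np.einsum("ij,ij->i", R @ Cinv, R)
    k_perm = (num / den) / expected
    p = (1.0 + np.sum(k_perm >= k_obs)) / (1.0 + n_perm)
    return k_obs, float(p)


def k_test(tree: Phylogeny, x, n_perm: int = 999, seed: int = 0, *,
           trait: str = "trait", rng: np.random.Generator | None = None) -> SignalResult:
    """Permutation test of Blomberg's K (shuffle trait values across tips)."""
    C, vec = _trait_vector(tree, x)
    _validate(vec)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    k_obs, p = _k_test_core(C, vec, n_perm, rng)
    return SignalResult(trait, "pool", None, len(vec), k_obs, p, n_perm)


def community_signal(tree: Phylogeny, x: pd.Series, comm: CommunityTable,
                     min_taxa: int = 4, n_perm: int = 999, seed: int = 0,
                     trait: str = "trait") -> pd.DataFrame:
    """Blomberg's K per grid cell, on the tree pruned to the cell's species.

    Cells with fewer than `min_taxa` species (default 4 — K on very few tips
    is statistically vacuous) or with zero trait variance are recorded as
    undefined rather than raised.  K is species-level; abundances in the
    community matrix only determine presence.
    """
    C, labels = tree.shared_path_matrix()
    labels = list(labels)
    pos = {l: i for i, l in enumerate(labels)}
    vec_full = x.reindex(labels).to_numpy(float)
    rows = []
    for i, (cell_id, row) in enumerate(comm.matrix.iterrows()):
        present = [s for s in row.index[row > 0] if s in pos]
        nt = len(present)
        if nt < min_taxa:
            rows.append((trait, "community", cell_id, nt, np.nan, np.nan, n_perm))
            continue
        ix = np.array([pos[s] for s in present])
        vec = vec_full[ix]
        if np.var(vec) == 0 or not np.all(np.isfinite(vec)):
            rows.append((trait, "community", cell_id, nt, np.nan, np.nan, n_perm))
            continue
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        k_obs, p = _k_test_core(C[np.ix_(ix, ix)], vec, n_perm, rng)
        rows.append((trait, "community", cell_id, nt, k_obs, p, n_perm))
    return pd.DataFrame(rows, columns=[
        "trait", "level", "cell_id", "n_taxa", "K", "p", "n_perm"]
    ).set_index("cell_id")


@dataclass(frozen=True)
class SignalComparison:
    mean_clustered: float
    mean_overdispersed: float
    n_clustered: int
    n_overdispersed: int
    t: float
    p: float


def compare_signal_by_pattern(signals: pd.DataFrame,
                              patterns: pd.Series) -> SignalComparison:
    """Welch t-test of community K between clustered and overdispersed cells.

    `signals` is the output of :func:`community_signal`; `patterns` maps
    cell_id to ``"clustered"``/``"overdispersed"`` (from
    :func:`~phylodisp.dispersion.classify_pattern` on SES.MPD).  Cells with
    undefined K or pattern are dropped.
    """
    merged = signals.join(patterns.rename("pattern"), how="inner")
    merged = merged.dropna(subset=["K", "pattern"])
    g1 = merged.loc[merged["pattern"] == "clustered", "K"].to_numpy()
    g2 = merged.loc[merged["pattern"] == "overdispersed", "K"].to_numpy()
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each pattern group needs at least 2 defined K values")
    if np.allclose(g1.var(ddof=1) + g2.var(ddof=1), 0.0) and g1.mean() == g2.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(g1, g2, equal_var=False)
    return SignalComparison(float(g1.mean()), float(g2.mean()),
                            len(g1), len(g2), float(t), float(p))
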