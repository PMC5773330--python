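"""Trait standardization, PCA reduction, and trait dendrograms.

Functional dispersion is measured with exactly the same MPD/MNTD/SES
machinery as phylogenetic dispersion, by substituting an ultrametric trait
dendrogram for the phylogeny.  This module prepares the trait table
(log-transform, z-score), optionally reduces it to the leading principal
components, and clusters species on Euclidean trait distance (UPGMA by
default) to yield a :class:`~phylodisp.tree_ops.DistanceMatrix` of cophenetic
trait distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .tree_ops import DistanceMatrix

__all__ = [
    "prepare_traits",
    "PCAReduction",
    "pca_reduce",
    "TraitDendrogram",
    "build_dendrogram",
]


def prepare_traits(raw: pd.DataFrame, log_columns="all") -> pd.DataFrame:
    """Log-transform and z-score a species x trait table.

    `log_columns` is a list of column names to natural-log transform, or
    ``"all"`` (the default, matching the usual treatment of size-like plant
    traits) or ``None``.  Species with any missing trait are dropped with a
    warning.  Z-scoring uses the sample SD (ddof=1).
    """
    df = raw.copy()
    incomplete = df.index[df.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(f"dropping {len(incomplete)} species with missing traits: "
                      f"{list(incomplete)}", stacklevel=2)
        df = df.drop(index=incomplete)
    cols = list(df.columns) if log_columns == "all" else list(log_columns or [])
    for c in cols:
        if (df[c] <= 0).any():
            raise ValueError(f"nonpositive values in log-flagged column {c!r}")
        df[c] = np.log(df[c])
    sd = df.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"zero-variance columns: {list(sd.index[sd == 0])}")
    return (df - df.mean()) / sd


@dataclass
class PCAReduction:
    """Species scores on the retained principal components."""

    scores: pd.DataFrame
    n_components: int
    explained_ratio: np.ndarray        # per retained component
    cumulative_variance: float         # fraction explained by retained PCs


def pca_reduce(tt: pd.DataFrame, variance_target: float = 0.90,
               n_components: int | None = None) -> PCAReduction:
    """Project the standardized trait table onto its leading PCs.

    Retains the smallest k with cumulative explained variance >=
    `variance_target`, or exactly `n_components` if given (mirroring analyses
    that fix "the first five PCs").  Rank-deficient tables retain at most
    their rank, with a warning.
    """
    if tt.shape[1] < 2 or tt.shape[0] < 3:
        raise ValueError("PCA needs >=2 traits and >=3 species")
    X = tt.to_numpy(float)
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    rank = int((pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]).sum())
    if n_components is not None:
        if n_components > rank:
            warnings.warn(f"requested {n_components} components but rank is "
                          f"{rank}; retaining {rank}", stacklevel=2)
        k = min(n_components, rank)
    else:
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        if k > rank:
            warnings.warn("variance target beyond matrix rank; retaining rank "
                          "components", stacklevel=2)
            k = rank
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAReduction(pd.DataFrame(scores[:, :k], index=tt.index, columns=cols),
                        k, ratios[:k], float(np.sum(ratios[:k])))


@dataclass
class TraitDendrogram:
    """UPGMA (or other linkage) dendrogram over species trait distances."""

    labels: tuple[str, ...]
    linkage: np.ndarray                 # scipy linkage matrix
    cophenetic: DistanceMatrix

    def to_newick(self) -> str:
        node = hierarchy.to_tree(self.linkage)

        def rec(nd, parent_height):
            if nd.is_leaf():
                bl = parent_height / 2.0
                return f"{self.labels[nd.id]}:{bl:.10g}"
            left = rec(nd.left, nd.dist)
            right = rec(nd.right, nd.dist)
            bl = (parent_height - nd.dist) / 2.0
            return f"({left},{right}):{bl:.10g}"

        root = hierarchy.to_tree(self.linkage)
        return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});\n"


def build_dendrogram(scores, method: str = "average") -> TraitDendrogram:
    """Cluster species on Euclidean trait distance.

    `scores` is a species x column DataFrame (PC scores or standardized
    traits) or a single Series (one trait).  Average linkage (UPGMA) is the
    default; its cophenetic distances are ultrametric, making the dendrogram
    a drop-in replacement for the phylogeny in the dispersion metrics.
    Cophenetic heights are node heights, so two species that merged at height
    h are at cophenetic distance h (identical rows merge at 0).
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    if len(scores) < 2:
        raise ValueError("need at least 2 species")
    labels = tuple(scores.index)
    X = scores.to_numpy(float)
    condensed = pdist(X)
    Z = hierarchy.linkage(condensed, method=method)
    coph = hierarchy.cophenet(Z)
    from scipy.spatial.distance import squareform
    dm = DistanceMatrix(labels, squareform(coph))
    return TraitDendrogram(labels, Z, dm)
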