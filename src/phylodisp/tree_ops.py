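"""Phylogeny ingestion, validation, cophenetic distances, and pruning.

The pipeline consumes a ready-made ultrametric phylogeny (e.g. an r8s-dated
tree) in newick format; nothing here infers trees.  The two objects every
downstream stage relies on are :class:`Phylogeny` (a validated wrapper around
a :class:`dendropy.Tree`) and :class:`DistanceMatrix` (a labelled symmetric
matrix of patristic distances, shared with the trait-dendrogram code so the
dispersion metrics apply to either basis unchanged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "Phylogeny",
    "TreeValidationError",
    "read_tree",
    "cophenetic",
    "prune",
]

ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    """Raised when a tree violates the pipeline's structural requirements."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labelled distance matrix (patristic or trait-cophenetic).

    Parameters
    ----------
    labels : tuple of str
        Ordered taxon identifiers.
    values : ndarray of shape (n, n)
        Symmetric, zero-diagonal distances in the same order as `labels`.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in distance matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    @property
    def n(self) -> int:
        return len(self.labels)

    def indexer(self, labels) -> np.ndarray:
        idx = self._index
        return np.fromiter((idx[l] for l in labels), dtype=np.intp, count=len(labels))

    def submatrix(self, labels) -> "DistanceMatrix":
        ix = self.indexer(labels)
        return DistanceMatrix(tuple(labels), self.values[np.ix_(ix, ix)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(tuple(df.index), df.to_numpy(dtype=float))


class Phylogeny:
    """A rooted tree with branch lengths, validated on construction.

    By default the tree must be ultrametric (all root-to-tip path lengths
    equal within relative tolerance 1e-6, the slack needed for rate-smoothed
    trees whose output is rounded).  Zero-length terminal branches produce
    zero patristic distances between distinct tips, which break the
    nearest-taxon metric; they are rejected unless ``allow_zero_terminals``.
    Polytomies are allowed throughout.
    """

    def __init__(self, tree: dendropy.Tree, *, require_ultrametric: bool = True,
                 allow_zero_terminals: bool = False) -> None:
        self._tree = tree
        labels = [leaf.taxon.label if leaf.taxon is not None else None
                  for leaf in tree.leaf_node_iter()]
        if any(l is None for l in labels):
            raise TreeValidationError("tree has unlabelled tips")
        if len(set(labels)) != len(labels):
            raise TreeValidationError("duplicate tip labels")
        if len(labels) < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise TreeValidationError("missing branch length")
            if edge.length < 0:
                raise TreeValidationError("negative branch length")
        for leaf in tree.leaf_node_iter():
            if leaf.edge.length == 0:
                if not allow_zero_terminals:
                    raise TreeValidationError(
                        "zero-length terminal branch (creates zero patristic "
                        "distances; pass allow_zero_terminals=True to override)")
                warnings.warn("zero-length terminal branch retained; nearest-"
                              "taxon distances may be zero", stacklevel=2)
        self._tip_labels = tuple(sorted(labels))
        depths = self._tip_depths()
        dmax = float(depths.max())
        self._depth = dmax
        if require_ultrametric and dmax > 0:
            if (dmax - depths.min()) > ULTRAMETRIC_RTOL * dmax:
                raise TreeValidationError(
                    "tree is not ultrametric (tip depth spread %.3g over depth "
                    "%.3g); pass require_ultrametric=False to override"
                    % (dmax - depths.min(), dmax))
        self._is_ultrametric = (dmax == 0) or \
            (dmax - depths.min()) <= ULTRAMETRIC_RTOL * dmax

    def _tip_depths(self) -> np.ndarray:
        out = []
        for leaf in self._tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node is not self._tree.seed_node:
                d += node.edge.length or 0.0
                node = node.parent_node
            out.append(d)
        return np.asarray(out)

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in sorted order (the canonical ordering for matrices)."""
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length (= the age of an ultrametric tree)."""
        return self._depth

    @property
    def is_ultrametric(self) -> bool:
        return self._is_ultrametric

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, **kwargs) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
            raise TreeValidationError(f"duplicate tip labels: {e}") from e
        except Exception as e:
            raise TreeValidationError(f"newick parse failure: {e}") from e
        return cls(tree, **kwargs)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True,
                                 unquoted_underscores=True)
        return s.strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    # -- distances ----------------------------------------------------------

    def cophenetic(self) -> DistanceMatrix:
        """Patristic distances d(i,j) = branch length summed along the path."""
        return cophenetic(self)

    def shared_path_matrix(self) -> tuple[np.ndarray, tuple[str, ...]]:
        """Brownian-motion covariance structure C.

        C[i,j] is the shared root-to-MRCA path length of tips i and j
        (C[i,i] = depth of tip i); computed from tip depths and patristic
        distances as (depth_i + depth_j - d_ij) / 2.
        """
        dm = self.cophenetic()
        depth_by_label = {}
        for leaf in self._tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node is not self._tree.seed_node:
                d += node.edge.length or 0.0
                node = node.parent_node
            depth_by_label[leaf.taxon.label] = d
        depths = np.array([depth_by_label[l] for l in dm.labels])
        C = (depths[:, None] + depths[None, :] - dm.values) / 2.0
        return C, dm.labels

    def prune(self, keep) -> "Phylogeny":
        return prune(self, keep)


def read_tree(path, *, require_ultrametric: bool = True,
              allow_zero_terminals: bool = False) -> Phylogeny:
    """Read and validate a newick tree from `path`.

    Non-ultrametric trees are rejected unless ``require_ultrametric=False``.
    """
    with open(path) as fh:
        text = fh.read()
    return Phylogeny.from_newick(text, require_ultrametric=require_ultrametric,
                                 allow_zero_terminals=allow_zero_terminals)


def cophenetic(tree: Phylogeny) -> DistanceMatrix:
    """Patristic distance matrix of `tree`, labels in sorted tip order."""
    if tree.n_tips < 2:
        raise TreeValidationError("cophenetic distances need at least 2 tips")
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace
            if t.label in set(tree.tip_labels)}
    labels = tree.tip_labels
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                       taxa[labels[j]])
    return DistanceMatrix(labels, d)


def prune(tree: Phylogeny, keep) -> Phylogeny:
    """Restrict `tree` to the taxa in `keep`.

    Unifurcations created by the removal are collapsed with their branch
    lengths summed, so patristic distances among kept tips are unchanged.
    """
    keep = set(keep)
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise TreeValidationError(f"unknown species: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeValidationError("prune requires at least 2 retained tips")
    sub = tree.dendropy_tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True)
    # extract_tree keeps the full taxon namespace; rebuild from newick so the
    # pruned Phylogeny's namespace holds only the retained taxa.
    txt = sub.as_string(schema="newick", suppress_rooting=True)
    return Phylogeny.from_newick(
        txt,
        require_ultrametric=False if not tree.is_ultrametric else True,
        allow_zero_terminals=True)
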