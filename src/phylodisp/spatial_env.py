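"""Spatial eigenvectors (dbMEM) and the polynomial environmental predictors.

Distance-based Moran's eigenvector maps describe spatial structure among
grid-cell centres at all scales the sampling design can resolve: the
inter-cell Euclidean distance matrix is truncated (distances beyond a
threshold t replaced by 4t), the truncated matrix is double-centred and
eigen-decomposed (PCoA), and the eigenvectors with positive eigenvalues form
an orthogonal spatial basis, broadest scales first.

The environmental predictor matrix expands every non-aspect variable into
centred first-, second- and third-degree polynomial terms and adds
sin(aspect) and cos(aspect); thirteen non-aspect variables plus aspect give
the canonical 41 predictor columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = ["MEMBasis", "dbmem", "env_expand"]

EIG_RTOL = 1e-8   # eigenvalues below this fraction of the largest are zero


@dataclass
class MEMBasis:
    """PCoA axes of the truncated spatial distance matrix.

    `vectors` columns are mutually orthogonal, centred, scaled by
    sqrt(eigenvalue), and ordered by descending (positive) eigenvalue —
    broadest spatial scales first.
    """

    cell_ids: tuple[str, ...]
    vectors: np.ndarray
    eigenvalues: np.ndarray
    truncation: float

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"MEM{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.vectors, index=pd.Index(self.cell_ids,
                            name="cell_id"), columns=cols)


def _auto_truncation(D: np.ndarray) -> float:
    mst = minimum_spanning_tree(D)
    return float(mst.data.max())


def dbmem(coords, truncation: float | None = None, cell_ids=None) -> MEMBasis:
    """dbMEM basis for point set `coords` (n x 2 array of cell centres).

    `truncation` defaults to the longest edge of the minimum spanning tree of
    the points (for a full regular grid, the cell spacing); distances above
    the threshold are replaced by four times the threshold before PCoA.  Only
    eigenvectors with positive eigenvalues (positive spatial autocorrelation)
    are returned.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or len(coords) < 3:
        raise ValueError("need at least 3 points with 2D coordinates")
    D = squareform(pdist(coords))
    if D.max() == 0:
        raise ValueError("all points identical")
    t = _auto_truncation(D) if truncation is None else float(truncation)
    if t <= 0:
        raise ValueError("truncation must be positive")
    Dstar = np.where(D <= t, D, 4.0 * t)
    np.fill_diagonal(Dstar, 0.0)
    n = len(D)
    A = -0.5 * Dstar ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ A @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > EIG_RTOL * vals[0]
    vals, vecs = vals[keep], vecs[:, keep]
    vectors = vecs * np.sqrt(vals)
    if cell_ids is None:
        cell_ids = tuple(str(i) for i in range(n))
    return MEMBasis(tuple(cell_ids), vectors, vals, t)


def env_expand(env: pd.DataFrame, aspect: str = "aspect",
               exclude=("x", "y")) -> pd.DataFrame:
    """Polynomial expansion of an environmental table.

    Every column except `aspect` and the coordinate columns in `exclude`
    contributes three centred power terms v, v^2, v^3 (powers taken after
    centring the raw variable, then each column re-centred, which limits
    collinearity among the powers); aspect (degrees) contributes sin and cos.
    Constant variables expand to all-zero columns and are dropped with a
    warning.
    """
    out = {}
    raw_vars = [c for c in env.columns if c != aspect and c not in exclude]
    for v in raw_vars:
        base = env[v].to_numpy(float)
        centred = base - base.mean()
        dropped = False
        for power, suffix in ((1, ""), (2, "^2"), (3, "^3")):
            col = centred ** power
            col = col - col.mean()
            if np.allclose(col, 0.0):
                dropped = True
                continue
            out[f"{v}{suffix}"] = col
        if dropped:
            warnings.warn(f"constant variable {v!r}: zero columns dropped",
                          stacklevel=2)
    if aspect in env.columns:
        rad = np.deg2rad(env[aspect].to_numpy(float))
        out["aspect_sin"] = np.sin(rad)
        out["aspect_cos"] = np.cos(rad)
    else:
        warnings.warn("no aspect column; sin/cos terms omitted", stacklevel=2)
    return pd.DataFrame(out, index=env.index)
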