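"""Forward selection and variation partitioning on adjusted R-squared.

The response here is univariate (one SES column per scale / size class /
metric / basis), so redundancy analysis reduces exactly to ordinary least
squares; the permutation machinery is the same as in the multivariate case.

Variation partitioning splits the variance of y explained by two predictor
sets X1 (environment and/or space) and X2 (phylogenetic dispersion) into
pure fractions a (X1), c (X2), a shared fraction b, and residual d, using
Ezekiel-adjusted R-squared:

    a = adjR2(X1 u X2) - adjR2(X2)
    c = adjR2(X1 u X2) - adjR2(X1)
    b = adjR2(X1) + adjR2(X2) - adjR2(X1 u X2)
    d = 1 - adjR2(X1 u X2)

Fractions can be slightly negative, an accepted artefact of the adjustment.
The significance of the pure X2 fraction is a partial permutation test:
residuals of y ~ X1 are permuted, the full model refitted, and the partial F
compared with its permutation distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "adj_r2",
    "ForwardSelection",
    "forward_select",
    "VarPartResult",
    "partition",
    "global_test",
]

_RANK_TOL = 1e-9


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if X is None:
        return np.empty((0, 0)), []
    if isinstance(X, pd.Series):
        X = X.to_frame()
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), [str(c) for c in X.columns]
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _ortho_basis(X: np.ndarray, n: int) -> np.ndarray:
    """Orthonormal basis of the centred column space (rank-revealing SVD)."""
    if X.size == 0:
        return np.empty((n, 0))
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    r = int((s > _RANK_TOL * (s[0] if s.size else 1.0)).sum())
    return U[:, :r]


def _r2(yc: np.ndarray, Q: np.ndarray) -> float:
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("response has zero variance")
    if Q.shape[1] == 0:
        return 0.0
    proj = Q.T @ yc
    return float(proj @ proj) / tss


def _adjust(r2: float, n: int, p: int) -> float:
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def adj_r2(y, X) -> float:
    """Ezekiel-adjusted R-squared of an OLS fit of y on X (with intercept).

    Collinear predictor sets are handled by a rank-revealing decomposition:
    the effective number of predictors is the rank of the centred X.
    """
    y = np.asarray(y, float)
    Xm, names = _as_matrix(X)
    if Xm.size and Xm.shape[0] != len(y):
        raise ValueError("X and y lengths differ")
    Q = _ortho_basis(Xm, len(y))
    if Xm.size and Q.shape[1] < Xm.shape[1]:
        warnings.warn("collinear predictors: rank %d < %d columns"
                      % (Q.shape[1], Xm.shape[1]), stacklevel=2)
    yc = y - y.mean()
    return _adjust(_r2(yc, Q), len(y), Q.shape[1])


def _perm_matrix(v: np.ndarray, n_perm: int, rng) -> np.ndarray:
    out = np.empty((n_perm, len(v)))
    for r in range(n_perm):
        out[r] = v[rng.permutation(len(v))]
    return out


def _partial_f(ssr_full, ssr_red, tss, df_extra, df_res):
    # clip tiny negative values from float cancellation (e.g. a saturated fit)
    num = np.maximum(ssr_full - ssr_red, 0.0) / df_extra
    den = np.maximum(tss - ssr_full, 0.0) / df_res
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    return np.where(den == 0.0, np.where(num > 0.0, np.inf, 0.0), f)


def global_test(y, X, n_perm: int = 999, seed: int = 0,
                rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Permutation F-test of the full model y ~ X (free permutation of y).

    Returns (F_obs, p) with p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    y = np.asarray(y, float)
    Xm, _ = _as_matrix(X)
    n = len(y)
    Q = _ortho_basis(Xm, n)
    if Q.shape[1] > n - 2:
        warnings.warn("candidate space rank %d >= n-1; truncating to n-2 "
                      "leading axes for the global test" % Q.shape[1],
                      stacklevel=2)
        Q = Q[:, :n - 2]
    p_eff = Q.shape[1]
    if p_eff == 0:
        raise ValueError("no candidate predictors")
    yc = y - y.mean()
    tss = float(yc @ yc)
    ssr = float(np.sum((Q.T @ yc) ** 2))
    df_res = n - p_eff - 1
    f_obs = float(_partial_f(ssr, 0.0, tss, p_eff, df_res))
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    P = _perm_matrix(yc, n_perm, rng)
    ssr_perm = np.sum((P @ Q) ** 2, axis=1)
    f_perm = _partial_f(ssr_perm, 0.0, tss, p_eff, df_res)
    p = float((1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm))
    return f_obs, p


@dataclass
class ForwardSelection:
    """Outcome of forward selection with the double stopping rule."""

    selected: list[str]
    steps: pd.DataFrame = field(repr=False)
    global_p: float = float("nan")
    global_adj_r2: float = float("nan")

    def matrix(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected]


def forward_select(y, X: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 9999, seed: int = 0,
                   global_gate: bool = True) -> ForwardSelection:
    """Stepwise predictor selection with permutation tests and the double
    stopping rule.

    At each step the candidate with the largest incremental R-squared is
    tested by permuting the residuals of the current reduced model and
    comparing the incremental F with its permutation distribution; selection
    stops when that p exceeds `alpha`, or when the cumulative adjusted
    R-squared of the selected set would exceed the adjusted R-squared of the
    full candidate model (which guards against inflated selections), or — if
    `global_gate` — immediately, when the full-model permutation test is
    itself nonsignificant.
    """
    y = np.asarray(y, float)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float),
                         columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
    n = len(y)
    names = list(X.columns)
    if not names:
        raise ValueError("no candidate predictors")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    yc = y - y.mean()
    tss = float(yc @ yc)

    Xc = X.to_numpy(float)
    Xc = Xc - Xc.mean(axis=0)
    norms0 = np.sum(Xc ** 2, axis=0)
    Q_full = _ortho_basis(Xc, n)
    if Q_full.shape[1] > n - 2:
        warnings.warn("candidate space rank %d >= n-1; double-stopping "
                      "ceiling uses the n-2 leading axes" % Q_full.shape[1],
                      stacklevel=2)
        Q_full = Q_full[:, :n - 2]
    adj_full = _adjust(_r2(yc, Q_full), n, Q_full.shape[1])
    f_g, p_g = global_test(y, X, n_perm=n_perm, rng=rng)
    steps = []
    selected: list[str] = []
    if global_gate and p_g > alpha:
        return ForwardSelection(selected, pd.DataFrame(
            steps, columns=["variable", "r2_cum", "adj_r2_cum", "f", "p"]),
            p_g, adj_full)

    # Candidates are added one at a time; XR holds each candidate's residual
    # after projecting out the selected set, so the best next candidate is a
    # single vectorized pass rather than one refit per candidate.
    XR = Xc.copy()
    Q = np.empty((n, 0))
    yr = yc.copy()
    ssr_sel = 0.0
    active = np.ones(len(names), dtype=bool)
    while active.any() and len(selected) < n - 2:
        res_norm = np.sum(XR ** 2, axis=0)
        usable = active & (res_norm > _RANK_TOL ** 2 * np.maximum(norms0, 1.0))
        if not usable.any():
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(usable, (XR.T @ yr) ** 2 / res_norm, -np.inf)
        j = int(np.argmax(gain))
        p_red = Q.shape[1]
        p_full = p_red + 1
        df_res = n - p_full - 1
        if df_res <= 0:
            break
        qnew = XR[:, j] / np.sqrt(res_norm[j])
        ssr_full = ssr_sel + float(qnew @ yc) ** 2
        r2_full = ssr_full / tss
        f_obs = float(_partial_f(ssr_full, ssr_sel, tss, 1, df_res))
        # permutation of the reduced-model residuals
        fitted_c = yc - yr
        E = _perm_matrix(yr, n_perm, rng)
        Ystar = fitted_c[None, :] + E
        Ystar = Ystar - Ystar.mean(axis=1, keepdims=True)
        tss_s = np.sum(Ystar ** 2, axis=1)
        ssr_red_s = np.sum((Ystar @ Q) ** 2, axis=1) if p_red else \
            np.zeros(n_perm)
        ssr_full_s = ssr_red_s + (Ystar @ qnew) ** 2
        f_perm = _partial_f(ssr_full_s, ssr_red_s, tss_s, 1, df_res)
        p_val = float((1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm))
        adj_cum = _adjust(r2_full, n, p_full)
        if p_val > alpha:
            break
        selected.append(names[j])
        steps.append((names[j], r2_full, adj_cum, f_obs, p_val))
        active[j] = False
        Q = np.hstack([Q, qnew[:, None]])
        yr = yr - qnew * float(qnew @ yr)
        XR = XR - np.outer(qnew, qnew @ XR)
        ssr_sel = ssr_full
        # double stopping rule: once the selected set's adjusted R2 reaches
        # the full candidate model's, further additions only overfit
        if adj_cum > adj_full + 1e-12:
            break

    return ForwardSelection(selected, pd.DataFrame(
        steps, columns=["variable", "r2_cum", "adj_r2_cum", "f", "p"]),
        p_g, adj_full)


@dataclass(frozen=True)
class VarPartResult:
    """Adjusted-R2 fractions of y against X1 (env/space) and X2 (phylogeny)."""

    response: str
    x1_label: str
    x2_label: str
    adj_r2_x1: float
    adj_r2_x2: float
    adj_r2_both: float
    a: float            # pure X1
    b: float            # shared
    c: float            # pure X2
    d: float            # residual
    p_pure_x2: float
    n_perm: int
    n: int


def partition(y, X1, X2, n_perm: int = 9999, seed: int = 0,
              response: str = "y", x1_label: str = "env+space",
              x2_label: str = "phylo") -> VarPartResult:
    """Two-set variation partitioning with a partial permutation test of the
    pure X2 fraction.

    X1 may be empty (no variables survived forward selection), in which case
    adjR2(X1) = 0 and the partial test reduces to the marginal test of X2.
    """
    y = np.asarray(y, float)
    n = len(y)
    X1m, _ = _as_matrix(X1)
    X2m, _ = _as_matrix(X2)
    if X2m.size == 0:
        raise ValueError("X2 must contain at least one column")
    Q1 = _ortho_basis(X1m, n)
    Q2 = _ortho_basis(X2m, n)
    both = np.hstack([x for x in (X1m, X2m) if x.size]) if X1m.size else X2m
    Qb = _ortho_basis(both, n)
    yc = y - y.mean()
    tss = float(yc @ yc)
    r1 = _adjust(_r2(yc, Q1), n, Q1.shape[1])
    r2_ = _adjust(_r2(yc, Q2), n, Q2.shape[1])
    rb = _adjust(_r2(yc, Qb), n, Qb.shape[1])
    a = rb - r2_
    c = rb - r1
    b = r1 + r2_ - rb
    d = 1.0 - rb
    # partial permutation test of X2 | X1
    p1, pb = Q1.shape[1], Qb.shape[1]
    df_extra, df_res = pb - p1, n - pb - 1
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    if df_extra == 0 or df_res <= 0:
        p_val = float("nan")
    else:
        ssr1 = float(np.sum((Q1.T @ yc) ** 2)) if p1 else 0.0
        ssrb = float(np.sum((Qb.T @ yc) ** 2))
        f_obs = float(_partial_f(ssrb, ssr1, tss, df_extra, df_res))
        fitted = Q1 @ (Q1.T @ yc) if p1 else np.zeros(n)
        resid = yc - fitted
        E = _perm_matrix(resid, n_perm, rng)
        Ystar = fitted[None, :] + E
        Ystar = Ystar - Ystar.mean(axis=1, keepdims=True)
        tss_s = np.sum(Ystar ** 2, axis=1)
        ssr1_s = np.sum((Ystar @ Q1) ** 2, axis=1) if p1 else np.zeros(n_perm)
        ssrb_s = np.sum((Ystar @ Qb) ** 2, axis=1)
        f_perm = _partial_f(ssrb_s, ssr1_s, tss_s, df_extra, df_res)
        p_val = float((1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm))
    return VarPartResult(response, x1_label, x2_label, r1, r2_, rb,
                         a, b, c, d, p_val, n_perm, n)
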