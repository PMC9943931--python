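"""Linear ordination core: Hellinger transform, orthogonal environmental
polynomials, (partial) redundancy analysis, adjusted R-squared,
permutation tests and forward selection.

RDA here is the multi-response least-squares projection of the centered
(transformed) community table on a predictor block, optionally after
residualizing both sides on a conditioning block.  Permutation tests use
the pseudo-F statistic; with conditioning, reduced-model residuals are
permuted (Freedman-Lane).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "hellinger",
    "ortho_env",
    "rda",
    "RdaFit",
    "adj_r2",
    "permutation_test",
    "forward_select",
]

_RANK_TOL = 1e-8


def hellinger(counts: np.ndarray) -> np.ndarray:
    """Square root of per-site relative abundance; all-zero rows stay zero."""
    a = np.asarray(counts, dtype=float)
    if (a < 0).any():
        raise ValueError("counts must be nonnegative")
    tot = a.sum(axis=1, keepdims=True)
    if (tot == 0).any():
        warnings.warn("all-zero rows left as zeros in Hellinger transform")
    out = np.zeros_like(a)
    np.divide(a, tot, out=out, where=tot > 0)
    return np.sqrt(out)


def ortho_env(E: np.ndarray, degree: int = 2) -> np.ndarray:
    """Centered orthonormal polynomial columns of degrees 1..degree of E.

    Built by QR of the centered Vandermonde block, so the columns are
    mutually orthogonal to machine precision and orthogonal to the
    intercept.
    """
    E = np.asarray(E, dtype=float)
    if np.unique(E).size < degree + 1:
        raise ValueError("E must carry at least degree + 1 distinct values")
    V = np.column_stack([E**k for k in range(degree + 1)])  # includes intercept
    Q, R = np.linalg.qr(V)
    cols = Q[:, 1:] * np.sign(np.diag(R)[1:])  # fix sign: leading coef > 0
    return cols


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    """Column basis of centered X, dropping collinear columns (QR pivoting)."""
    Xc = X - X.mean(axis=0)
    if Xc.size == 0:
        return np.empty((X.shape[0], 0))
    Q, R, piv = linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > _RANK_TOL * max(diag[0], 1.0)).sum()) if diag.size else 0
    if rank < Xc.shape[1]:
        warnings.warn("rank-deficient predictors: collinear columns dropped")
    return Q[:, :rank]


@dataclass
class RdaFit:
    r2: float
    adj_r2: float
    rank: int  # number of independent constrained axes used
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    lc_scores: np.ndarray = field(repr=False)  # site scores, scaling 1
    eigenvalues: np.ndarray = field(repr=False)


def rda(Y: np.ndarray, X: np.ndarray, Z: np.ndarray | None = None) -> RdaFit:
    """(Partial) redundancy analysis of response table Y on predictors X.

    With a conditioning block Z, both Y and X are first residualized on
    [1, Z]; R-squared is then the semipartial fraction of the conditioned
    response's variance.  Canonical (linear-combination) site scores in
    scaling 1 are the fitted values projected on the species axes of the
    fitted-value SVD.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    ss_raw = float((Yc**2).sum())
    if Z is not None and np.asarray(Z).size:
        Qz = _orthonormal_basis(np.asarray(Z, float))
        Yc = Yc - Qz @ (Qz.T @ Yc)
        X = np.asarray(X, float)
        X = X - X.mean(axis=0)
        X = X - Qz @ (Qz.T @ X)
    Qx = _orthonormal_basis(np.asarray(X, float))
    p = Qx.shape[1]
    if p >= n:
        raise ValueError("more predictors than sites")
    fitted = Qx @ (Qx.T @ Yc)
    ss_tot = float((Yc**2).sum())
    ss_fit = float((fitted**2).sum())
    # a response conditioned away entirely carries no explainable variance
    r2 = ss_fit / ss_tot if ss_tot > 1e-10 * max(ss_raw, 1e-300) else 0.0
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s > _RANK_TOL * (s[0] if s.size else 1.0)
    lc = U[:, keep] * s[keep]  # distances among sites preserved (scaling 1)
    eig = (s[keep] ** 2) / max(n - 1, 1)
    return RdaFit(
        r2=r2,
        adj_r2=adj_r2(r2, n, p) if n > p + 1 else float("nan"),
        rank=p,
        fitted=fitted,
        residuals=Yc - fitted,
        lc_scores=lc,
        eigenvalues=eig,
    )


def adj_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment; may be negative."""
    if p == 0:
        return r2
    if n <= p + 1:
        raise ValueError("adjustment undefined for n <= p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _pseudo_f(ss_fit: np.ndarray, ss_res: np.ndarray, p: int, df_res: int) -> np.ndarray:
    return (ss_fit / p) / (ss_res / df_res)


def permutation_test(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """One-tailed (upper) permutation test of the (partial) RDA pseudo-F.

    Without conditioning, rows of Y are permuted; with conditioning, the
    reduced-model residuals are permuted and the Z-fit added back.
    Returns (observed F, p) with p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    if n_perm < 99:
        warnings.warn("n_perm < 99: permutation p-value is unreliable")
    rng = rng or np.random.default_rng(seed)
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    if Z is not None and np.asarray(Z).size:
        Qz = _orthonormal_basis(np.asarray(Z, float))
        Xr = np.asarray(X, float) - np.asarray(X, float).mean(axis=0)
        Xr = Xr - Qz @ (Qz.T @ Xr)
        q = Qz.shape[1]
    else:
        Qz = None
        Xr = np.asarray(X, float)
        q = 0
    Qx = _orthonormal_basis(Xr)
    p = Qx.shape[1]
    if p == 0:
        return 0.0, 1.0
    df_res = n - p - q - 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom for the test")

    def stat(Ymat: np.ndarray) -> float:
        if Qz is not None:
            Ymat = Ymat - Qz @ (Qz.T @ Ymat)
        ss_fit = float(((Qx.T @ Ymat) ** 2).sum())
        ss_tot = float((Ymat**2).sum())
        return _pseudo_f(ss_fit, max(ss_tot - ss_fit, 1e-300), p, df_res)

    if Qz is not None:
        # Freedman-Lane: permute residuals of the reduced model
        fit_z = Qz @ (Qz.T @ Yc)
        res_z = Yc - fit_z
        obs = stat(Yc)
        hits = 0
        for _ in range(n_perm):
            Yp = fit_z + res_z[rng.permutation(n)]
            if stat(Yp) >= obs:
                hits += 1
    else:
        obs = stat(Yc)
        hits = 0
        for _ in range(n_perm):
            if stat(Yc[rng.permutation(n)]) >= obs:
                hits += 1
    return obs, (1.0 + hits) / (1.0 + n_perm)


def forward_select(
    Y: np.ndarray,
    candidates: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[int]:
    """Classical forward selection of predictor columns for RDA.

    The global model (all candidates) must pass the permutation test at
    ``alpha`` first; candidates are then added greedily by gain in R2,
    each admission gated by a partial permutation test conditioned on the
    already-selected block.  Returns the selected column indices, in
    order of entry (possibly empty).
    """
    Y = np.asarray(Y, dtype=float)
    C = np.asarray(candidates, dtype=float)
    if C.ndim != 2 or C.shape[1] == 0:
        return []
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    # keep the global model testable: never consider more columns than df allow
    max_cols = n - 2
    _, p_global = permutation_test(Y, C[:, :max_cols], n_perm=n_perm, rng=rng)
    if p_global > alpha:
        return []
    selected: list[int] = []
    remaining = list(range(C.shape[1]))
    while remaining and len(selected) < max_cols - 1:
        Z = C[:, selected] if selected else None
        gains = []
        for j in remaining:
            Xj = C[:, list(selected) + [j]]
            gains.append(rda(Y, Xj).r2)
        best = remaining[int(np.argmax(gains))]
        _, p_best = permutation_test(Y, C[:, [best]], Z=Z, n_perm=n_perm, rng=rng)
        if p_best > alpha:
            break
        selected.append(best)
        remaining.remove(best)
    return selected
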