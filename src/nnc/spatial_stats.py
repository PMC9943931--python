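"""Spatial eigenfunctions and spatial statistics for the window sites.

PCNM follows the classic construction: truncate the Euclidean distance
matrix at the longest minimum-spanning-tree edge, replace larger
distances by four times the threshold, double-center the squared
distances and keep the positive-eigenvalue principal coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

__all__ = [
    "PcnmBasis",
    "pcnm",
    "sturges_classes",
    "Correlogram",
    "morans_i",
    "morans_correlogram",
    "mantel",
]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class PcnmBasis:
    vectors: np.ndarray = field(repr=False)  # (n_sites, k), unit columns
    eigenvalues: np.ndarray
    threshold: float

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


def pcnm(distances: np.ndarray, threshold: float | None = None) -> PcnmBasis:
    """Principal coordinates of the truncated neighbor matrix.

    ``threshold`` defaults to the longest edge of the minimum spanning
    tree of the distance graph (which keeps all sites connected).
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sites")
    if np.allclose(D, 0):
        raise ValueError("degenerate coordinates: all distances zero")
    if threshold is None:
        mst = minimum_spanning_tree(D)
        threshold = float(mst.data.max())
    Dt = np.where(D > threshold, 4.0 * threshold, D)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = w > _EIG_TOL * max(abs(w).max(), 1.0)
    return PcnmBasis(vectors=V[:, keep], eigenvalues=w[keep], threshold=threshold)


def sturges_classes(n_pairs: int) -> int:
    """Sturges rule on the number of site pairs: ceil(1 + log2(n))."""
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    return int(np.ceil(1.0 + np.log2(n_pairs)))


@dataclass(frozen=True)
class Correlogram:
    I: np.ndarray  # Moran's I per distance class (NaN where undefined)
    breaks: np.ndarray  # class edges, length n_classes + 1
    n_pairs: np.ndarray  # site pairs per class


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with an arbitrary binary/real weight matrix (zero diagonal)."""
    z = np.asarray(values, float)
    z = z - z.mean()
    denom = float((z * z).sum())
    if denom == 0:
        raise ValueError("constant values: Moran's I undefined")
    W = float(weights.sum())
    if W == 0:
        raise ValueError("empty weight matrix")
    n = z.size
    return float(n / W * (z @ weights @ z) / denom)


def distance_class_breaks(distances: np.ndarray, n_classes: int) -> np.ndarray:
    """Equal-width classes spanning (0, max distance]."""
    d = np.asarray(distances, float)
    off = d[np.triu_indices_from(d, k=1)]
    return np.linspace(0.0, float(off.max()), n_classes + 1)


def morans_correlogram(
    values: np.ndarray, distances: np.ndarray, n_classes: int | None = None
) -> Correlogram:
    """Moran's I per equal-width distance class with binary weights.

    ``n_classes`` defaults to the Sturges rule on the number of pairs.
    """
    D = np.asarray(distances, float)
    n = D.shape[0]
    if n_classes is None:
        n_classes = sturges_classes(n * (n - 1) // 2)
    breaks = distance_class_breaks(D, n_classes)
    I = np.full(n_classes, np.nan)
    npairs = np.zeros(n_classes, dtype=int)
    eye = np.eye(n, dtype=bool)
    for k in range(n_classes):
        lo, hi = breaks[k], breaks[k + 1]
        w = (D > lo) & (D <= hi) & ~eye
        npairs[k] = int(w.sum()) // 2
        if npairs[k] > 0:
            I[k] = morans_i(values, w.astype(float))
    return Correlogram(I=I, breaks=breaks, n_pairs=npairs)


def mantel(
    A: np.ndarray,
    B: np.ndarray,
    tail: str = "lower",
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two symmetric species-pair tables.

    r is the Pearson correlation over the off-diagonal upper-triangle
    entries; the null distribution permutes rows and columns of B
    simultaneously.  ``tail`` is 'lower' (default, the alternative r < 0),
    'upper', or 'two-sided'.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("tables must be square and of equal shape")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 species")
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    a = a - a.mean()
    sa = np.sqrt((a * a).sum())
    b = B[iu]
    b = b - b.mean()
    sb = np.sqrt((b * b).sum())
    if sa == 0 or sb == 0:
        raise ValueError("zero variance in one of the tables")
    r_obs = float((a * b).sum() / (sa * sb))
    rng = rng or np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B[np.ix_(perm, perm)][iu]
        bp = bp - bp.mean()
        sbp = np.sqrt((bp * bp).sum())
        r_p = float((a * bp).sum() / (sa * sbp)) if sbp > 0 else 0.0
        if tail == "lower":
            hits += r_p <= r_obs
        elif tail == "upper":
            hits += r_p >= r_obs
        else:
            hits += abs(r_p) >= abs(r_obs)
    return r_obs, (1.0 + hits) / (1.0 + n_perm)


def correlogram_distance_matrix(correlograms: np.ndarray) -> np.ndarray:
    """Euclidean distances between species' Moran's I vectors (rows)."""
    C = np.asarray(correlograms, float)
    diff = C[:, None, :] - C[None, :, :]
    return np.sqrt(np.nansum(diff**2, axis=-1))
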