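"""Species-neutral and functional diversity of the model communities.

All metrics are computed on abundances pooled over the window sites.
Functional similarity between two species is the overlap of the Gaussian
niche densities of their guilds (species of the same guild overlap
completely), so the dissimilarity feeding Rao's quadratic entropy is
``1 - overlap``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

__all__ = [
    "gaussian_overlap",
    "similarity_matrix",
    "simpson",
    "rao_q",
    "uniqueness_redundancy",
    "initial_rao",
    "DiversityMetrics",
    "community_diversity",
]


def gaussian_overlap(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """Overlap of two normal densities: the integral of their pointwise
    minimum over the real line, in [0, 1].

    Equal variances reduce to ``2 * Phi(-|mu1 - mu2| / (2 sigma))``;
    unequal variances are handled via the two crossing points of the
    densities.  Falls back to numeric integration if the analytic branch
    degenerates.
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("tolerances must be positive")
    if mu1 == mu2 and sigma1 == sigma2:
        return 1.0
    if np.isclose(sigma1, sigma2):
        return float(2.0 * norm.cdf(-abs(mu1 - mu2) / (2.0 * sigma1)))
    # order so that sigma_a < sigma_b; the narrow density exceeds the wide
    # one exactly between the two roots of the log-density difference
    (mu_a, s_a), (mu_b, s_b) = sorted(
        [(mu1, sigma1), (mu2, sigma2)], key=lambda t: t[1]
    )
    a = 1.0 / s_b**2 - 1.0 / s_a**2  # < 0
    b = 2.0 * (mu_a / s_a**2 - mu_b / s_b**2)
    c = mu_b**2 / s_b**2 - mu_a**2 / s_a**2 + 2.0 * np.log(s_b / s_a)
    disc = b * b - 4.0 * a * c
    if disc <= 0:  # pragma: no cover - numerically degenerate
        return float(
            quad(
                lambda x: min(norm.pdf(x, mu1, sigma1), norm.pdf(x, mu2, sigma2)),
                min(mu1, mu2) - 10 * max(sigma1, sigma2),
                max(mu1, mu2) + 10 * max(sigma1, sigma2),
                limit=200,
            )[0]
        )
    r = np.sqrt(disc)
    x1, x2 = sorted([(-b - r) / (2 * a), (-b + r) / (2 * a)])
    # min density: wide one on [x1, x2], narrow one outside
    inner = norm.cdf(x2, mu_b, s_b) - norm.cdf(x1, mu_b, s_b)
    outer = 1.0 - (norm.cdf(x2, mu_a, s_a) - norm.cdf(x1, mu_a, s_a))
    return float(np.clip(inner + outer, 0.0, 1.0))


def similarity_matrix(optima: np.ndarray, tolerances: np.ndarray) -> np.ndarray:
    """Species-by-species Gaussian-overlap similarity (symmetric, unit
    diagonal; species with identical niches have similarity 1)."""
    mu = np.asarray(optima, float)
    sig = np.asarray(tolerances, float)
    n = mu.size
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = gaussian_overlap(mu[i], sig[i], mu[j], sig[j])
    return sim


def simpson(abundances: np.ndarray) -> tuple[float, float]:
    """Simpson diversity D = 1 - sum(p^2) and its effective number 1/sum(p^2)."""
    a = np.asarray(abundances, float)
    if a.sum() <= 0:
        raise ValueError("abundances must not be all zero")
    p = a / a.sum()
    s2 = float((p * p).sum())
    return 1.0 - s2, 1.0 / s2


def rao_q(abundances: np.ndarray, dissimilarity: np.ndarray) -> tuple[float, float]:
    """Rao's quadratic entropy Q = p' d p and its effective number 1/(1-Q)."""
    a = np.asarray(abundances, float)
    d = np.asarray(dissimilarity, float)
    if d.shape != (a.size, a.size):
        raise ValueError("dissimilarity shape does not match abundances")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be symmetric")
    p = a / a.sum()
    q = float(p @ d @ p)
    return q, 1.0 / (1.0 - q)


def uniqueness_redundancy(
    abundances: np.ndarray, dissimilarity: np.ndarray
) -> tuple[float, float, bool]:
    """Functional uniqueness U = Q/D and redundancy R = 1 - U.

    Returns (U, R, defined).  A single-species community has D = 0; U is
    then reported as 0 with ``defined=False``.
    """
    D, _ = simpson(abundances)
    if D <= 0:
        return 0.0, 1.0, False
    Q, _ = rao_q(abundances, dissimilarity)
    U = Q / D
    return float(U), float(1.0 - U), True


def initial_rao(sizes: np.ndarray, optima: np.ndarray, tolerances: np.ndarray) -> float:
    """Rao's Q of the t0 system treating each guild as one species with
    relative abundance size / JM."""
    sizes = np.asarray(sizes, float)
    if sizes.size == 1:
        return 0.0
    d = 1.0 - similarity_matrix(optima, tolerances)
    q, _ = rao_q(sizes, d)
    return q


@dataclass(frozen=True)
class DiversityMetrics:
    D: float  # Simpson probability form
    D_eff: float  # inverse-Simpson effective number
    Q: float  # Rao quadratic entropy
    Q_eff: float
    U: float  # functional uniqueness Q / D
    R: float  # functional redundancy 1 - U
    U_defined: bool
    n_species: int
    n_guilds: int


def community_diversity(
    counts: np.ndarray, optima: np.ndarray, tolerances: np.ndarray, guild_ids: np.ndarray
) -> DiversityMetrics:
    """All window-level metrics from a site-by-species count table and the
    per-species niche metadata."""
    pooled = np.asarray(counts).sum(axis=0)
    keep = pooled > 0
    pooled = pooled[keep]
    mu = np.asarray(optima, float)[keep]
    sig = np.asarray(tolerances, float)[keep]
    gid = np.asarray(guild_ids)[keep]
    # species in the same guild have identical niches (overlap exactly 1),
    # so only guild-level overlaps need integrating
    ug, first, inv = np.unique(gid, return_index=True, return_inverse=True)
    sim_g = similarity_matrix(mu[first], sig[first])
    d = 1.0 - sim_g[inv][:, inv]
    D, D_eff = simpson(pooled)
    Q, Q_eff = rao_q(pooled, d)
    U, R, defined = uniqueness_redundancy(pooled, d)
    return DiversityMetrics(
        D=D,
        D_eff=D_eff,
        Q=Q,
        Q_eff=Q_eff,
        U=U,
        R=R,
        U_defined=defined,
        n_species=int(pooled.size),
        n_guilds=int(np.unique(gid).size),
    )
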