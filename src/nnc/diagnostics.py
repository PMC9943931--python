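"""Analysis pipeline over a converged window community table.

Variation partitioning splits the Hellinger-transformed abundance
variance between forward-selected environmental polynomials and PCNM
spatial eigenfunctions on the adjusted-R2 scale; component significance
is judged by upper-tail permutation tests, with species-environment
claims based on the *pure* environmental fraction.  When at least two
guilds coexist and the pure environmental fraction is significant, the
habitat (guild) structure is recovered by k-means on the canonical site
scores with the simple-structure-index criterion, and spatial structure
is re-modeled hierarchically within and among the habitat patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .landscape import Window
from .ordination import forward_select, hellinger, ortho_env, permutation_test, rda
from .spatial_stats import (
    correlogram_distance_matrix,
    mantel,
    morans_correlogram,
    pcnm,
    sturges_classes,
)

__all__ = [
    "VarpartResult",
    "variation_partition",
    "classify_components",
    "GuildStructure",
    "simple_structure_index",
    "guild_structure",
    "HierarchicalResult",
    "hierarchical_model",
    "AutocorrResult",
    "autocorrelation_analysis",
]


@dataclass
class VarpartResult:
    env: float  # adjusted [a+b]
    spatial: float  # adjusted [b+c]
    pure_env: float  # [a]
    pure_spatial: float  # [c]
    shared: float  # [b]
    residual: float  # [d]
    total_explained: float  # [a+b+c]
    p_env: float
    p_pure_env: float
    p_spatial: float
    p_pure_spatial: float
    env_selected: list[int]
    spatial_selected: list[int]
    flagged_empty: bool = False

    @property
    def rel_env(self) -> float:
        """Environmental fraction relative to the total explained variation."""
        return self.env / self.total_explained if self.total_explained > 0 else 0.0

    @property
    def rel_pure_spatial(self) -> float:
        return self.pure_spatial / self.total_explained if self.total_explained > 0 else 0.0


def variation_partition(
    Y: np.ndarray,
    env_candidates: np.ndarray,
    spatial_candidates: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    select_env: bool = False,
) -> VarpartResult:
    """Partition the (transformed) community variance between the
    environmental and spatial predictor sets.

    The spatial set (many PCNM candidates) is forward-selected; the
    environmental set (two orthogonal polynomials) enters whole by
    default, so the component tests are defined in every scenario —
    gating them through selection would mask the anisotropy bias the
    single-guild scenarios are designed to expose.  Pass
    ``select_env=True`` to forward-select the environmental set too.
    """
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(x) for x in rng.integers(0, 2**31 - 1, 3))
    if select_env:
        env_sel = forward_select(Y, env_candidates, alpha=alpha, n_perm=n_perm, seed=s1)
    else:
        env_sel = list(range(np.asarray(env_candidates).shape[1]))
    spa_sel = forward_select(Y, spatial_candidates, alpha=alpha, n_perm=n_perm, seed=s2)
    E = env_candidates[:, env_sel]
    S = spatial_candidates[:, spa_sel]
    if not env_sel and not spa_sel:
        return VarpartResult(
            env=0.0, spatial=0.0, pure_env=0.0, pure_spatial=0.0, shared=0.0,
            residual=1.0, total_explained=0.0, p_env=1.0, p_pure_env=1.0,
            p_spatial=1.0, p_pure_spatial=1.0, env_selected=[], spatial_selected=[],
            flagged_empty=True,
        )
    ab = rda(Y, E).adj_r2 if env_sel else 0.0
    bc = rda(Y, S).adj_r2 if spa_sel else 0.0
    if env_sel and spa_sel:
        abc = rda(Y, np.column_stack([E, S])).adj_r2
    else:
        abc = ab if env_sel else bc
    a = abc - bc
    c = abc - ab
    b = ab + bc - abc
    rng2 = np.random.default_rng(s3)
    p_env = permutation_test(Y, E, n_perm=n_perm, rng=rng2)[1] if env_sel else 1.0
    p_spa = permutation_test(Y, S, n_perm=n_perm, rng=rng2)[1] if spa_sel else 1.0
    p_pure_env = (
        permutation_test(Y, E, Z=S, n_perm=n_perm, rng=rng2)[1]
        if env_sel and spa_sel
        else p_env
    )
    p_pure_spa = (
        permutation_test(Y, S, Z=E, n_perm=n_perm, rng=rng2)[1]
        if env_sel and spa_sel
        else p_spa
    )
    return VarpartResult(
        env=ab,
        spatial=bc,
        pure_env=a,
        pure_spatial=c,
        shared=b,
        residual=1.0 - abc,
        total_explained=abc,
        p_env=p_env,
        p_pure_env=p_pure_env,
        p_spatial=p_spa,
        p_pure_spatial=p_pure_spa,
        env_selected=list(env_sel),
        spatial_selected=list(spa_sel),
    )


def classify_components(
    varpart: VarpartResult, n_guilds_present: int, alpha: float = 0.05
) -> list[str]:
    """Label the interpretable components of a partition.

    Single-guild communities can only show a *false environmental*
    component (pure environmental fraction significant despite niche
    equivalence) or a *true spatial* one (spatial significant while the
    environmental side is not).  Multi-guild communities show a *true
    environmental* component when the pure environmental fraction is
    significant, and a *spatial* component otherwise eligible for the
    hierarchical decomposition.
    """
    labels: list[str] = []
    env_signif = varpart.p_env <= alpha
    pure_env_signif = varpart.p_pure_env <= alpha
    spatial_signif = varpart.p_spatial <= alpha or varpart.p_pure_spatial <= alpha
    if n_guilds_present <= 1:
        if pure_env_signif:
            labels.append("false environmental")
        if spatial_signif and not (env_signif or pure_env_signif):
            labels.append("true spatial")
    else:
        if pure_env_signif:
            labels.append("true environmental")
        if spatial_signif:
            labels.append("spatial")
    return labels


def simple_structure_index(centers: np.ndarray, sizes: np.ndarray) -> float:
    """Weighted simple structure index of a k-means partition.

    Combines, per variable, the span of the cluster means, the sizes of
    the two most contrasting clusters, and the deviation of the variable
    mean from the grand mean of the centers.
    """
    centers = np.asarray(centers, float)
    sizes = np.asarray(sizes, float)
    ncl, nvar = centers.shape
    cord = np.argsort(centers, axis=0)
    cmaxi = cord[-1, :]
    cmini = cord[0, :]
    span = centers.max(axis=0) - centers.min(axis=0)
    meanmean = centers.mean()
    absmdif = np.abs(centers.mean(axis=0) - meanmean)
    csizemax = sizes[cmaxi]
    csizemin = sizes[cmini]
    hiestw = nvar * max(csizemax.max(), csizemin.max()) * np.exp(-absmdif.min())
    return float((span * np.exp(-absmdif)) @ np.sqrt(csizemax * csizemin) / hiestw)


@dataclass
class GuildStructure:
    assignments: np.ndarray  # habitat type per site
    k: int
    ssi_profile: dict[int, float]
    p_value: float
    significant: bool


def guild_structure(
    Y: np.ndarray,
    lc_scores: np.ndarray,
    k_max: int | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> GuildStructure:
    """Habitat types from k-means over canonical site scores (scaling 1),
    k chosen by the simple structure index; significance by a permutation
    RDA of the habitat-factor dummies against the response.

    Note the circularity: the clusters are derived from Y's own canonical
    scores, so the test is anti-conservative; it mirrors the original
    protocol and is recorded as such.
    """
    n = lc_scores.shape[0]
    if lc_scores.size == 0 or np.allclose(lc_scores.std(axis=0), 0):
        raise ValueError("degenerate canonical scores")
    if k_max is None:
        k_max = min(10, n // 5)
    k_max = max(k_max, 2)
    rng = np.random.default_rng(seed)
    profile: dict[int, float] = {}
    best = None
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(lc_scores)
        sizes = np.bincount(lab, minlength=k)
        if (sizes == 0).any():
            continue
        ssi = simple_structure_index(km.cluster_centers_, sizes)
        profile[k] = ssi
        if best is None or ssi > best[0]:
            best = (ssi, k, lab)
    if best is None:
        raise ValueError("no valid k-means partition found")
    _, k, lab = best
    dummies = np.eye(k)[lab]
    _, p = permutation_test(Y, dummies, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
    return GuildStructure(
        assignments=lab, k=k, ssi_profile=profile, p_value=p, significant=p <= alpha
    )


def _patch_pcnm_blocks(
    window: Window, assignments: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Among- and within-habitat spatial candidate blocks.

    Among: PCNM of the habitat patch-centroid distances, expanded to the
    member sites of each patch.  Within: per habitat type with >= 3
    sites, a block PCNM of its sites, zero elsewhere.  Returns (A, W,
    skipped habitat ids).
    """
    pts = np.column_stack([window.x, window.y]).astype(float)
    k = int(assignments.max()) + 1
    centroids = np.vstack([pts[assignments == h].mean(axis=0) for h in range(k)])
    if k >= 3:
        dc = np.sqrt(((centroids[:, None] - centroids[None]) ** 2).sum(-1))
        basis = pcnm(dc)
        A = basis.vectors[assignments]
    else:
        A = np.empty((pts.shape[0], 0))
    blocks = []
    skipped: list[int] = []
    for h in range(k):
        idx = np.flatnonzero(assignments == h)
        if idx.size < 3:
            skipped.append(h)
            continue
        sub = window.distances[np.ix_(idx, idx)]
        try:
            vb = pcnm(sub).vectors
        except ValueError:
            skipped.append(h)
            continue
        blk = np.zeros((pts.shape[0], vb.shape[1]))
        blk[idx] = vb
        blocks.append(blk)
    W = np.column_stack(blocks) if blocks else np.empty((pts.shape[0], 0))
    return A, W, skipped


@dataclass
class HierarchicalResult:
    total_explained: float
    habitat_fraction: float  # adjusted R2 of the habitat dummies alone
    rel_env: float
    rel_pure_spatial: float
    among_selected: list[int]
    within_selected: list[int]
    p_spatial_residual: float
    skipped_habitats: list[int]
    context_fits: dict[int, np.ndarray] = field(default_factory=dict)


def hierarchical_model(
    Y: np.ndarray,
    window: Window,
    structure: GuildStructure,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> HierarchicalResult:
    """Re-model the spatial structure within and among the habitat patches
    on the residual variation of the habitat-factor model."""
    rng = np.random.default_rng(seed)
    lab = structure.assignments
    k = structure.k
    H = np.eye(k)[lab]
    A, W, skipped = _patch_pcnm_blocks(window, lab)
    n_candidates = A.shape[1] + W.shape[1]
    fit_h = rda(Y, H)
    if n_candidates == 0:
        return HierarchicalResult(
            total_explained=fit_h.adj_r2, habitat_fraction=fit_h.adj_r2,
            rel_env=1.0, rel_pure_spatial=0.0, among_selected=[],
            within_selected=[], p_spatial_residual=1.0, skipped_habitats=skipped,
        )
    AW = np.column_stack([A, W]) if A.size else W
    sel = forward_select(
        fit_h.residuals, AW, alpha=alpha, n_perm=n_perm,
        seed=int(rng.integers(2**31 - 1)),
    )
    among_sel = [j for j in sel if j < A.shape[1]]
    within_sel = [j - A.shape[1] for j in sel if j >= A.shape[1]]
    Ssel = AW[:, sel]
    if sel:
        _, p_spa = permutation_test(
            Y, Ssel, Z=H, n_perm=n_perm, rng=np.random.default_rng(int(rng.integers(2**31 - 1)))
        )
        total = rda(Y, np.column_stack([H, Ssel])).adj_r2
        pure_spatial = total - fit_h.adj_r2
    else:
        p_spa = 1.0
        total = fit_h.adj_r2
        pure_spatial = 0.0
    rel_env = fit_h.adj_r2 / total if total > 0 else 0.0
    rel_ps = pure_spatial / total if total > 0 else 0.0
    # per-habitat-context fitted values of the within-patch spatial model
    contexts: dict[int, np.ndarray] = {}
    if within_sel:
        Wsel = W[:, within_sel]
        fit_w = rda(fit_h.residuals, Wsel)
        for h in range(k):
            idx = np.flatnonzero(lab == h)
            if idx.size >= 3 and h not in skipped:
                contexts[h] = fit_w.fitted[idx]
    return HierarchicalResult(
        total_explained=total,
        habitat_fraction=fit_h.adj_r2,
        rel_env=rel_env,
        rel_pure_spatial=rel_ps,
        among_selected=among_sel,
        within_selected=within_sel,
        p_spatial_residual=p_spa,
        skipped_habitats=skipped,
        context_fits=contexts,
    )


@dataclass
class AutocorrResult:
    mantel_r: float
    mantel_p: float
    n_species_used: int
    component: str
    degenerate: bool = False


def autocorrelation_analysis(
    fitted: np.ndarray,
    distances: np.ndarray,
    n_classes: int | None = None,
    component: str = "",
    n_perm: int = 999,
    seed: int | None = None,
) -> AutocorrResult:
    """Mantel test (lower tail) between the species-pair correlation table
    of a component's fitted values and the table of distances between the
    species' Moran's I correlograms.

    ``n_classes`` defaults to the Sturges rule on the site-pair count (the
    overall-model convention); environmental contexts pass 3 or 2.
    """
    F = np.asarray(fitted, float)
    n_sites = F.shape[0]
    sd = F.std(axis=0)
    keep = sd > 1e-12
    F = F[:, keep]
    if F.shape[1] < 3:
        return AutocorrResult(np.nan, np.nan, int(F.shape[1]), component, degenerate=True)
    if n_classes is None:
        n_classes = sturges_classes(n_sites * (n_sites - 1) // 2)
    A = np.corrcoef(F.T)
    correlos = np.vstack(
        [morans_correlogram(F[:, j], distances, n_classes).I for j in range(F.shape[1])]
    )
    B = correlogram_distance_matrix(correlos)
    try:
        r, p = mantel(A, B, tail="lower", n_perm=n_perm, seed=seed)
    except ValueError:
        return AutocorrResult(np.nan, np.nan, int(F.shape[1]), component, degenerate=True)
    return AutocorrResult(r, p, int(F.shape[1]), component)


def context_n_classes(n_sites_in_context: int) -> int:
    """Three distance classes when the context holds >= 45 site pairs,
    else two."""
    pairs = n_sites_in_context * (n_sites_in_context - 1) // 2
    return 3 if pairs >= 45 else 2


def window_predictors(window: Window, E_window: np.ndarray):
    """Convenience: the (env, spatial) candidate blocks for a window."""
    env = ortho_env(E_window, degree=2)
    spa = pcnm(window.distances).vectors
    return env, spa


def transform_community(counts: np.ndarray) -> np.ndarray:
    """Hellinger-transformed window community table."""
    return hellinger(counts)
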