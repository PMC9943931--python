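"""Guilds, initial guild population sizes, and the two initial labelings.

A guild is a group of species sharing one environmental niche (optimum
``mu``, tolerance ``sigma``); point-mutation speciation conserves the
guild, so the guild set can only shrink over a run.  Two initializations
share all randomness: *monodominance* (one species per guild) and
*infinite diversity* (one species per individual).  At equal seeds the
two initial states differ only in the species-labeling map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import GridSpec

__all__ = [
    "Guild",
    "PopulationState",
    "draw_guilds",
    "draw_guild_sizes",
    "initialize_population",
    "quadruple_pool",
    "min_tolerance",
    "TOLERANCE_EXCLUDE_DEFAULT",
]

#: scenarios whose narrowest guild tolerance falls below this are flagged
TOLERANCE_EXCLUDE_DEFAULT = 0.0052


@dataclass(frozen=True)
class Guild:
    guild_id: int
    optimum: float  # mu, in [0, 1]
    tolerance: float  # sigma, in (0, 10]

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class PopulationState:
    """All JM individuals, slot-addressed: individual ``i`` lives at site
    ``i // J``, slot ``i % J``.

    ``species`` ids: initial species occupy ``[0, n_initial)``; ids of
    species founded at step ``t >= 1`` are ``JM + (t - 1) * JM + i`` for
    founding slot ``i``, hence identical between coupled runs.
    ``founder`` is the slot index of the t0 ancestor, inherited by all
    descendants.
    """

    grid: GridSpec
    species: np.ndarray  # (JM,) int64
    guild: np.ndarray  # (JM,) int64
    founder: np.ndarray  # (JM,) int64
    guilds: list[Guild]
    n_initial_species: int
    step: int = 0
    # species id -> (guild id, birth step); initial species have birth 0
    species_meta: dict[int, tuple[int, int]] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        JM = self.grid.JM
        for name in ("species", "guild", "founder"):
            if getattr(self, name).shape != (JM,):
                raise ValueError(f"{name} must have shape ({JM},)")
        if self.species_meta is None:
            self.species_meta = {
                int(s): (int(self.guild[self.species == s][0]), 0)
                for s in np.unique(self.species)
            }

    @property
    def site_of(self) -> np.ndarray:
        return np.arange(self.grid.JM) // self.grid.J

    def site_by_species(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense count matrix (n_sites, n_extant_species) and the species ids
        labeling its columns."""
        ids, codes = np.unique(self.species, return_inverse=True)
        counts = np.zeros((self.grid.n_sites, ids.size), dtype=np.int64)
        np.add.at(counts, (self.site_of, codes), 1)
        return counts, ids

    def extant_guilds(self) -> np.ndarray:
        return np.unique(self.guild)

    def to_frame(self) -> pd.DataFrame:
        J = self.grid.J
        i = np.arange(self.grid.JM)
        return pd.DataFrame(
            {
                "site": i // J,
                "slot": i % J,
                "species": self.species,
                "guild": self.guild,
                "founder": self.founder,
            }
        )


def draw_guilds(g: int, seed: int) -> list[Guild]:
    """Draw ``g`` guild niches: optimum ~ U(0, 1), tolerance ~ U(0, 10]."""
    if g < 1:
        raise ValueError("need at least one guild")
    rng = np.random.default_rng(seed)
    optima = rng.uniform(0.0, 1.0, size=g)
    # U(0, 10]: complement of the half-open uniform keeps sigma > 0
    tols = 10.0 * (1.0 - rng.random(g))
    return [Guild(i, float(mu), float(s)) for i, (mu, s) in enumerate(zip(optima, tols))]


def min_tolerance(guilds: list[Guild]) -> float:
    return min(g.tolerance for g in guilds)


def draw_guild_sizes(JM: int, g: int, seed: int) -> np.ndarray:
    """Split JM individuals over g guilds at g - 1 sorted uniform cutpoints.

    Cutpoints are distinct integers in [1, JM - 1] (sampled without
    replacement) so every guild receives at least one individual.
    """
    if not 1 <= g <= JM:
        raise ValueError("need 1 <= g <= JM")
    if g == 1:
        return np.array([JM], dtype=np.int64)
    rng = np.random.default_rng(seed)
    cuts = np.sort(rng.choice(np.arange(1, JM), size=g - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [JM]]))
    return sizes.astype(np.int64)


def sizes_from_cutpoints(JM: int, cuts) -> np.ndarray:
    """Successive differences of (0, sorted cutpoints, JM)."""
    cuts = np.sort(np.asarray(cuts, dtype=np.int64))
    return np.diff(np.concatenate([[0], cuts, [JM]])).astype(np.int64)


def quadruple_pool(sizes: np.ndarray) -> np.ndarray:
    """Large-system pool: same guild niches, each guild size times four."""
    return np.asarray(sizes, dtype=np.int64) * 4


def initialize_population(
    grid: GridSpec,
    guilds: list[Guild],
    sizes: np.ndarray,
    mode: str,
    seed: int,
) -> PopulationState:
    """Place the initial individuals uniformly at random over the JM slots.

    The slot permutation and founder codes depend only on the seed, not on
    ``mode``: coupled monodominance / infinite-diversity runs start from
    identical (site, guild, founder) triples.
    """
    if mode not in ("monodominance", "infinite_diversity"):
        raise ValueError("mode must be 'monodominance' or 'infinite_diversity'")
    sizes = np.asarray(sizes, dtype=np.int64)
    if sizes.size != len(guilds):
        raise ValueError("one size per guild required")
    if (sizes < 1).any():
        raise ValueError("guild sizes must be >= 1")
    if sizes.sum() != grid.JM:
        raise ValueError("guild sizes must sum to JM")
    rng = np.random.default_rng(seed)
    guild_of_individual = np.repeat(np.arange(len(guilds), dtype=np.int64), sizes)
    perm = rng.permutation(grid.JM)  # shared-randomness slot assignment
    guild = np.empty(grid.JM, dtype=np.int64)
    guild[perm] = guild_of_individual
    founder = np.arange(grid.JM, dtype=np.int64)
    if mode == "monodominance":
        species = guild.copy()
        n_initial = len(guilds)
        meta = {i: (i, 0) for i in range(len(guilds))}
    else:
        species = founder.copy()
        n_initial = grid.JM
        meta = {int(i): (int(guild[i]), 0) for i in range(grid.JM)}
    return PopulationState(
        grid=grid,
        species=species,
        guild=guild,
        founder=founder,
        guilds=list(guilds),
        n_initial_species=n_initial,
        species_meta=meta,
    )


def pool_table(state: PopulationState) -> pd.DataFrame:
    """Export of the extant species pool."""
    ids = np.unique(state.species)
    rows = []
    for s in ids:
        gid, birth = state.species_meta[int(s)]
        gld = state.guilds[gid]
        rows.append((int(s), gid, gld.optimum, gld.tolerance, birth))
    return pd.DataFrame(
        rows, columns=["species", "guild", "optimum", "tolerance", "birth_step"]
    )
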