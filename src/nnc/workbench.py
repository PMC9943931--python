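"""Scenario enumeration, batch execution and summaries.

The full design: the small (20x20, J=16) system pairs with the two lower
dispersal rates and the large (40x40) system with the highest one; per
(dispersal, environmental structure) cell the small system runs 4
multi-guild levels x 5 niche draws x 5 size draws plus 25 single-guild
niche draws (125 scenarios), the large system runs 5 guild levels x 5
niche draws x 1 size draw.  Totals: 750 + 75 = 825.

Niche and size draws are seeded from (master seed, guild level, replicate)
only, so every (dispersal, structure) cell starts from the same pools.
The reduced preset shrinks the lattice to 8x8/J=8 with a faster
speciation rate so a batch converges in seconds per scenario.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, diversity, engine, landscape, species_pool

__all__ = [
    "SystemPreset",
    "ScenarioSpec",
    "DesignManifest",
    "enumerate_scenarios",
    "exclusion_filter",
    "run_scenario",
    "summarize",
    "PAPER_FULL",
    "REDUCED",
]


@dataclass(frozen=True)
class SystemPreset:
    name: str
    small_grid: tuple[int, int]
    large_grid: tuple[int, int]
    J: int
    nu: float
    max_steps: int
    window_size: int
    wave_period: int
    hump_period: int
    g_levels: tuple[int, ...]
    n_niche_reps: int
    n_size_reps: int
    n_single_guild_reps: int
    m_small: tuple[float, ...] = (0.01, 0.09)
    m_large: tuple[float, ...] = (0.81,)


PAPER_FULL = SystemPreset(
    name="paper_full",
    small_grid=(20, 20),
    large_grid=(40, 40),
    J=16,
    nu=0.001,
    max_steps=200_000,
    window_size=10,
    wave_period=20,
    hump_period=5,
    g_levels=(1, 8, 40, 160, 500),
    n_niche_reps=5,
    n_size_reps=5,
    n_single_guild_reps=25,
)

#: scaled-down analog: whole batches converge on one CPU in minutes
REDUCED = SystemPreset(
    name="reduced",
    small_grid=(8, 8),
    large_grid=(8, 8),
    J=8,
    nu=0.01,
    max_steps=20_000,
    window_size=6,
    wave_period=8,
    hump_period=4,
    g_levels=(1, 8, 40),
    n_niche_reps=1,
    n_size_reps=1,
    n_single_guild_reps=1,
)

PRESETS = {"paper_full": PAPER_FULL, "reduced": REDUCED}

ENV_STRUCTURES = landscape.ENV_STRUCTURES


def _derive_seed(master_seed: int, *fields) -> int:
    """Deterministic per-stage seed from mixed str/int/float components
    (stable across processes, unlike builtin str hashing)."""
    key = [master_seed]
    for f in fields:
        if isinstance(f, (int, np.integer)):
            key.append(int(f) % (2**31))
        else:
            key.append(zlib.crc32(str(f).encode()))
    return int(np.random.SeedSequence(key).generate_state(1)[0])


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: int
    system: str  # 'small' | 'large'
    m: float
    structure: str
    g: int
    niche_rep: int
    size_rep: int
    preset: str
    master_seed: int

    def seeds(self) -> dict[str, int]:
        """Stage seeds; niche/size depend only on (g, replicate)."""
        ms = self.master_seed
        return {
            "env": _derive_seed(ms, "env", self.structure, self.system),
            "niche": _derive_seed(ms, "niche", self.g, self.niche_rep),
            "size": _derive_seed(ms, "size", self.g, self.size_rep),
            "run": _derive_seed(ms, "run", self.scenario_id),
            "analysis": _derive_seed(ms, "analysis", self.scenario_id),
        }


@dataclass
class DesignManifest:
    preset: SystemPreset
    scenarios: list[ScenarioSpec]
    excluded: dict[int, bool] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return len(self.scenarios)

    def count(self, system: str | None = None, m: float | None = None,
              structure: str | None = None) -> int:
        out = 0
        for s in self.scenarios:
            if system is not None and s.system != system:
                continue
            if m is not None and s.m != m:
                continue
            if structure is not None and s.structure != structure:
                continue
            out += 1
        return out


def enumerate_scenarios(design: str = "paper_full", master_seed: int = 0) -> DesignManifest:
    preset = PRESETS[design]
    scenarios: list[ScenarioSpec] = []
    sid = 0

    def add(system, m, structure, g, niche_rep, size_rep):
        nonlocal sid
        scenarios.append(
            ScenarioSpec(sid, system, m, structure, g, niche_rep, size_rep,
                         preset.name, master_seed)
        )
        sid += 1

    if design == "paper_full":
        multi = [g for g in preset.g_levels if g > 1]
        for m in preset.m_small:
            for structure in ENV_STRUCTURES:
                for g in multi:
                    for nr in range(preset.n_niche_reps):
                        for sr in range(preset.n_size_reps):
                            add("small", m, structure, g, nr, sr)
                for nr in range(preset.n_single_guild_reps):
                    add("small", m, structure, 1, nr, 0)
        for m in preset.m_large:
            for structure in ENV_STRUCTURES:
                for g in preset.g_levels:
                    for nr in range(preset.n_niche_reps):
                        add("large", m, structure, g, nr, 0)
    elif design == "reduced":
        # 21 scenarios: the small-system analog carries g in {1, 8, 40},
        # the large-system (high-m) analog g = 8 only
        for m in preset.m_small:
            for structure in ENV_STRUCTURES:
                for g in preset.g_levels:
                    add("small", m, structure, g, 0, 0)
        for m in preset.m_large:
            for structure in ENV_STRUCTURES:
                add("large", m, structure, 8, 0, 0)
    else:  # pragma: no cover
        raise ValueError(f"unknown design {design!r}")
    return DesignManifest(preset=preset, scenarios=scenarios)


def scenario_inputs(spec: ScenarioSpec):
    """Materialize (grid, env, guilds, sizes, params) for a scenario."""
    preset = PRESETS[spec.preset]
    seeds = spec.seeds()
    shape = preset.small_grid if spec.system == "small" else preset.large_grid
    grid = landscape.GridSpec(width=shape[0], height=shape[1], J=preset.J)
    env = landscape.generate_environment(
        grid, spec.structure,
        seed=seeds["env"],
        wave_period=preset.wave_period,
        hump_period=preset.hump_period,
    )
    guilds = species_pool.draw_guilds(spec.g, seeds["niche"])
    small_JM = preset.small_grid[0] * preset.small_grid[1] * preset.J
    sizes = species_pool.draw_guild_sizes(small_JM, spec.g, seeds["size"])
    if spec.system == "large" and grid.JM == 4 * small_JM:
        sizes = species_pool.quadruple_pool(sizes)
    elif grid.JM != small_JM:  # pragma: no cover - preset misconfiguration
        raise ValueError("large grid must hold 4x the small system")
    params = engine.SimulationParams(
        nu=preset.nu, m=spec.m, max_steps=preset.max_steps, seed=seeds["run"]
    )
    return grid, env, guilds, sizes, params


def exclusion_filter(
    manifest: DesignManifest,
    threshold: float = species_pool.TOLERANCE_EXCLUDE_DEFAULT,
) -> DesignManifest:
    """Flag scenarios whose narrowest guild tolerance falls below the
    exclusion threshold (they stay in the manifest, marked excluded)."""
    for spec in manifest.scenarios:
        guilds = species_pool.draw_guilds(spec.g, spec.seeds()["niche"])
        manifest.excluded[spec.scenario_id] = (
            species_pool.min_tolerance(guilds) < threshold
        )
    return manifest


def window_community(state, window):
    """Site-by-species counts over the window plus per-species niche data."""
    counts, ids = state.site_by_species()
    counts = counts[window.site_ids]
    keep = counts.sum(axis=0) > 0
    counts, ids = counts[:, keep], ids[keep]
    gids = np.array([state.species_meta[int(s)][0] for s in ids])
    mu = np.array([state.guilds[g].optimum for g in gids])
    sig = np.array([state.guilds[g].tolerance for g in gids])
    return counts, ids, gids, mu, sig


def run_scenario(
    spec: ScenarioSpec,
    alpha: float = 0.05,
    n_perm: int = 199,
    tolerance_exclude: float = species_pool.TOLERANCE_EXCLUDE_DEFAULT,
) -> dict:
    """Full pipeline for one scenario; returns a JSON-serializable record."""
    preset = PRESETS[spec.preset]
    grid, env, guilds, sizes, params = scenario_inputs(spec)
    seeds = spec.seeds()
    record: dict = {
        "scenario_id": spec.scenario_id,
        "system": spec.system,
        "m": spec.m,
        "structure": spec.structure,
        "g": spec.g,
        "niche_rep": spec.niche_rep,
        "size_rep": spec.size_rep,
        "preset": spec.preset,
        "seeds": seeds,
        "min_tolerance": species_pool.min_tolerance(guilds),
        "excluded": species_pool.min_tolerance(guilds) < tolerance_exclude,
    }
    state, traj = engine.run_to_convergence(grid, env, guilds, sizes, params)
    record.update(
        converged=traj.converged,
        t_convergence=traj.t_convergence,
        t_guild_stationary=traj.t_guild_stationary or 0,
        time_ratio=traj.time_ratio,
        n_guilds_final=int(state.extant_guilds().size),
        n_species_final=int(np.unique(state.species).size),
    )
    if not traj.converged:
        record["statistics_skipped"] = True
        return record

    window = landscape.extract_window(grid, size=preset.window_size)
    counts, ids, gids, mu, sig = window_community(state, window)
    metrics = diversity.community_diversity(counts, mu, sig, gids)
    q0 = diversity.initial_rao(
        sizes,
        np.array([g.optimum for g in guilds]),
        np.array([g.tolerance for g in guilds]),
    )
    record.update(
        n_species_window=metrics.n_species,
        n_guilds_window=metrics.n_guilds,
        D_eff=metrics.D_eff,
        Q=metrics.Q,
        Q_eff=metrics.Q_eff,
        U=metrics.U,
        R=metrics.R,
        U_defined=metrics.U_defined,
        Q0=q0,
    )

    if metrics.n_species < 2:
        record["statistics_skipped"] = True
        return record
    Y = diagnostics.transform_community(counts)
    E_window = env.values[window.site_ids]
    env_cand, spa_cand = diagnostics.window_predictors(window, E_window)
    vp = diagnostics.variation_partition(
        Y, env_cand, spa_cand, alpha=alpha, n_perm=n_perm, seed=seeds["analysis"]
    )
    record["varpart"] = {
        k: getattr(vp, k)
        for k in (
            "env", "spatial", "pure_env", "pure_spatial", "shared", "residual",
            "total_explained", "p_env", "p_pure_env", "p_spatial",
            "p_pure_spatial", "env_selected", "spatial_selected", "flagged_empty",
        )
    }
    record["rel_env"] = vp.rel_env
    record["rel_pure_spatial"] = vp.rel_pure_spatial
    labels = diagnostics.classify_components(vp, metrics.n_guilds, alpha=alpha)
    record["component_labels"] = labels

    # autocorrelation analysis per interpretable component of the overall model
    autocorr = {}
    if vp.env_selected and ("false environmental" in labels or "true environmental" in labels):
        fit_env = diagnostics.rda(Y, env_cand[:, vp.env_selected]).fitted
        res = diagnostics.autocorrelation_analysis(
            fit_env, window.distances, component="environmental",
            n_perm=n_perm, seed=seeds["analysis"] + 1,
        )
        autocorr["environmental"] = dataclasses.asdict(res)
    if vp.spatial_selected and ("true spatial" in labels or "spatial" in labels):
        fit_spa = diagnostics.rda(Y, spa_cand[:, vp.spatial_selected]).fitted
        res = diagnostics.autocorrelation_analysis(
            fit_spa, window.distances, component="spatial",
            n_perm=n_perm, seed=seeds["analysis"] + 2,
        )
        autocorr["spatial"] = dataclasses.asdict(res)
    record["autocorrelation"] = autocorr

    # hierarchical guild structure (multi-guild, significant pure env only)
    if metrics.n_guilds >= 2 and vp.p_pure_env <= alpha and vp.env_selected:
        fit = diagnostics.rda(Y, np.column_stack([env_cand[:, vp.env_selected]]))
        try:
            gs = diagnostics.guild_structure(
                Y, fit.lc_scores, alpha=alpha, n_perm=n_perm,
                seed=seeds["analysis"] + 3,
            )
            record["guild_structure"] = {
                "k": gs.k,
                "p_value": gs.p_value,
                "significant": gs.significant,
                "ssi_profile": {str(k): v for k, v in gs.ssi_profile.items()},
            }
            if gs.significant:
                hm = diagnostics.hierarchical_model(
                    Y, window, gs, alpha=alpha, n_perm=n_perm,
                    seed=seeds["analysis"] + 4,
                )
                record["hierarchical"] = {
                    "total_explained": hm.total_explained,
                    "habitat_fraction": hm.habitat_fraction,
                    "rel_env": hm.rel_env,
                    "rel_pure_spatial": hm.rel_pure_spatial,
                    "p_spatial_residual": hm.p_spatial_residual,
                    "n_among": len(hm.among_selected),
                    "n_within": len(hm.within_selected),
                    "skipped_habitats": hm.skipped_habitats,
                }
                ctx_results = {}
                for h, fv in hm.context_fits.items():
                    idx = np.flatnonzero(gs.assignments == h)
                    d = window.distances[np.ix_(idx, idx)]
                    res = diagnostics.autocorrelation_analysis(
                        fv, d,
                        n_classes=diagnostics.context_n_classes(idx.size),
                        component=f"context-{h}",
                        n_perm=n_perm, seed=seeds["analysis"] + 5 + h,
                    )
                    ctx_results[str(h)] = dataclasses.asdict(res)
                record["hierarchical_contexts"] = ctx_results
        except ValueError as exc:
            record["guild_structure"] = {"error": str(exc)}
    return record


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def write_records(records: list[dict], path) -> None:
    Path(path).write_text(json.dumps(records, indent=1, default=_json_default))


def read_records(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def summarize(records: list[dict]) -> pd.DataFrame:
    """Per-(m, structure, guild-level) stratum summary of a record batch."""
    rows = []
    for r in records:
        if not r.get("converged") or r.get("excluded"):
            continue
        vp = r.get("varpart", {})
        rows.append(
            {
                "m": r["m"],
                "structure": r["structure"],
                "g": r["g"],
                "time_ratio": r.get("time_ratio"),
                "U": r.get("U"),
                "R": r.get("R"),
                "Q0": r.get("Q0"),
                "rel_env": r.get("rel_env"),
                "rel_pure_spatial": r.get("rel_pure_spatial"),
                "pure_env_signif": (
                    vp.get("p_pure_env", 1.0) <= 0.05 if vp else None
                ),
                "spatial_signif": (
                    vp.get("p_spatial", 1.0) <= 0.05 if vp else None
                ),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (
        df.groupby(["m", "structure", "g"])
        .agg(
            n=("time_ratio", "size"),
            median_time_ratio=("time_ratio", "median"),
            median_U=("U", "median"),
            median_R=("R", "median"),
            median_rel_env=("rel_env", "median"),
            median_rel_pure_spatial=("rel_pure_spatial", "median"),
            pure_env_rejection_rate=("pure_env_signif", "mean"),
            spatial_rejection_rate=("spatial_signif", "mean"),
        )
        .reset_index()
    )
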