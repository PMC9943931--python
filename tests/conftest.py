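import numpy as np
import pytest

from nnc import engine, landscape, species_pool


@pytest.fixture(scope="session")
def small_grid():
    return landscape.GridSpec(width=8, height=8, J=8)


@pytest.fixture(scope="session")
def humps_env(small_grid):
    return landscape.generate_environment(
        small_grid, "humps", seed=3, hump_period=4
    )


@pytest.fixture(scope="session")
def converged_multi_guild(small_grid, humps_env):
    """One converged monodominance run of a multi-guild reduced scenario,
    shared across statistic tests."""
    guilds = species_pool.draw_guilds(8, seed=11)
    sizes = species_pool.draw_guild_sizes(small_grid.JM, 8, seed=12)
    params = engine.SimulationParams(nu=0.01, m=0.09, max_steps=20_000, seed=5)
    state, traj = engine.run_to_convergence(
        small_grid, humps_env, guilds, sizes, params
    )
    assert traj.converged
    return state, traj, guilds, sizes


@pytest.fixture(scope="session")
def converged_single_guild(small_grid, humps_env):
    guilds = species_pool.draw_guilds(1, seed=21)
    sizes = np.array([small_grid.JM])
    params = engine.SimulationParams(nu=0.01, m=0.09, max_steps=20_000, seed=6)
    state, traj = engine.run_to_convergence(
        small_grid, humps_env, guilds, sizes, params
    )
    assert traj.converged
    return state, traj, guilds, sizes
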