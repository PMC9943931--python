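"""Torus lattices, dispersal weights, environmental gradients and the
central model-community window.

The system is a rectangular grid of local communities wrapped onto a
torus.  Sites are indexed row-major: ``site = y * width + x`` (``y``
slowest).  Each site holds a fixed number of individuals ``J`` and one
environmental value ``E`` in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "GridSpec",
    "EnvironmentField",
    "NeighborWeights",
    "Window",
    "build_torus_weights",
    "generate_environment",
    "extract_window",
    "approximate_scale",
    "landscape_table",
    "read_landscape_table",
]

ENV_STRUCTURES = ("random", "linear", "humps")

#: one full triangle wave of the linear gradient spans this many columns
DEFAULT_WAVE_PERIOD = 20
#: hump spacing (sites) along each axis
DEFAULT_HUMP_PERIOD = 5


@dataclass(frozen=True)
class GridSpec:
    """Dimensions of the torus lattice of local communities."""

    width: int
    height: int
    J: int = 16
    torus: bool = True

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError("grid must be at least 3x3")
        if self.J < 1:
            raise ValueError("J must be >= 1")

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    @property
    def JM(self) -> int:
        """Total number of individuals in the system."""
        return self.n_sites * self.J

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (x, y) arrays in site order."""
        s = np.arange(self.n_sites)
        return s % self.width, s // self.width


@dataclass(frozen=True)
class EnvironmentField:
    values: np.ndarray  # E per site, shape (n_sites,)
    structure: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("environmental values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class NeighborWeights:
    """Row-stochastic site-by-site dispersal weights (Moore 8-neighborhood)."""

    matrix: sparse.csr_matrix

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class Window:
    """The centered block of model communities sampled from the system.

    Distances are plain Euclidean: the window represents an area sampled
    from a larger system, so the torus wrap is not visible to the analyst.
    """

    site_ids: np.ndarray  # indices into the full grid
    x: np.ndarray  # local coordinates, 0-based
    y: np.ndarray
    distances: np.ndarray = field(repr=False)  # pairwise Euclidean

    @property
    def n_sites(self) -> int:
        return self.site_ids.size


def build_torus_weights(grid: GridSpec) -> NeighborWeights:
    """Dispersal weights: 1/8 to each of the 8 torus neighbors of a site."""
    if grid.width < 3 or grid.height < 3:
        raise ValueError("neighborhoods self-overlap on grids smaller than 3x3")
    w, h = grid.width, grid.height
    x, y = grid.coords()
    rows, cols = [], []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            nx = (x + dx) % w
            ny = (y + dy) % h
            rows.append(np.arange(grid.n_sites))
            cols.append(ny * w + nx)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.full(rows.size, 1.0 / 8.0)
    mat = sparse.csr_matrix((data, (rows, cols)), shape=(grid.n_sites,) * 2)
    return NeighborWeights(matrix=mat)


def _uniform_ladder(n: int) -> np.ndarray:
    """n equally spaced values spanning [0, 1]."""
    return np.linspace(0.0, 1.0, n)


def _rank_to_ladder(pattern: np.ndarray) -> np.ndarray:
    """Map a field onto the uniform ladder, monotone in value.

    Ties (exact periodic copies of the tile pattern) are broken in
    *reverse* site order; with the row-major site layout this keeps the
    ladder step across the wrap-around seam no larger than the matching
    interior step.
    """
    n = pattern.size
    order = np.lexsort((-np.arange(n), pattern))
    ladder = np.empty(n)
    ladder[order] = _uniform_ladder(n)
    return ladder


def generate_environment(
    grid: GridSpec,
    structure: str,
    seed: int | None = None,
    *,
    wave_period: int = DEFAULT_WAVE_PERIOD,
    hump_period: int = DEFAULT_HUMP_PERIOD,
) -> EnvironmentField:
    """Generate the environmental gradient ``E`` in one of three structures.

    random
        An equally spaced ladder of ``n_sites`` values on [0, 1] randomly
        permuted over sites: exact uniform representation, no spatial
        correlation.  Requires ``seed``.
    linear
        Triangle wave along x (one full period per ``wave_period``
        columns), constant in y, continuous across the wrap.
    humps
        Periodic isotropic bumps with period ``hump_period`` in x and y,
        rank-transformed to the uniform ladder; one strict local maximum
        per period tile.
    """
    if structure not in ENV_STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; expected one of {ENV_STRUCTURES}")
    x, y = grid.coords()
    if structure == "random":
        if seed is None:
            raise ValueError("the random structure requires a seed")
        rng = np.random.default_rng(seed)
        values = rng.permutation(_uniform_ladder(grid.n_sites))
    elif structure == "linear":
        if grid.width % wave_period:
            raise ValueError("wave_period must divide the grid width")
        # half-step phase offset keeps each E value equally represented
        phase = ((x + 0.5) % wave_period) / wave_period
        values = np.where(phase < 0.5, 2.0 * phase, 2.0 - 2.0 * phase)
    else:  # humps
        p = hump_period
        if grid.width % p or grid.height % p:
            raise ValueError("hump_period must divide both grid dimensions")
        # separable unimodal bumps; fractional offsets avoid within-tile ties
        pattern = np.cos(2 * np.pi * (x + 0.25) / p) + np.cos(2 * np.pi * (y + 0.15) / p)
        values = _rank_to_ladder(pattern)
    return EnvironmentField(values=values, structure=structure)


def extract_window(grid: GridSpec, size: int = 10) -> Window:
    """The centered ``size`` x ``size`` block of model communities."""
    if grid.width < size or grid.height < size:
        raise ValueError(f"grid too small for a {size}x{size} window")
    x0 = (grid.width - size) // 2
    y0 = (grid.height - size) // 2
    lx, ly = np.meshgrid(np.arange(size), np.arange(size))
    lx, ly = lx.ravel(), ly.ravel()
    site_ids = (ly + y0) * grid.width + (lx + x0)
    pts = np.column_stack([lx, ly]).astype(float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return Window(site_ids=site_ids, x=lx, y=ly, distances=d)


def approximate_scale(m: float, nu: float) -> int:
    """Characteristic number of lattice steps a lineage diffuses before
    speciation, floor(sqrt(m / nu))."""
    if nu <= 0:
        raise ValueError("speciation rate must be positive")
    if not (nu <= m <= 1.0):
        raise ValueError("require 0 < nu <= m <= 1")
    return int(np.floor(np.sqrt(m / nu)))


def local_maxima_count(grid: GridSpec, env: EnvironmentField) -> int:
    """Number of strict local maxima of E under 8-neighbor torus comparison."""
    w, h = grid.width, grid.height
    field2d = env.values.reshape(h, w)
    strict = np.ones((h, w), dtype=bool)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            strict &= field2d > np.roll(np.roll(field2d, dy, axis=0), dx, axis=1)
    return int(strict.sum())


def landscape_table(grid: GridSpec, env: EnvironmentField) -> pd.DataFrame:
    """Plain table export: one row per local community (row-major site order)."""
    x, y = grid.coords()
    return pd.DataFrame(
        {"site": np.arange(grid.n_sites), "x": x, "y": y, "E": env.values}
    )


def read_landscape_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["site", "x", "y", "E"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"landscape table must have columns {expected}")
    return df
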