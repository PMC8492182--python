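"""Equation-based model: delayed-Fisher front speed over a least-cost surface.

The colonization front of a growing, diffusing population advances at an
asymptotic speed given by Fisher's reaction-diffusion result corrected for
the generation lag of human reproduction:

    v = 2 * sqrt(a * D) / (1 + a * tau / 2),    D = <Delta>^2 / (4 * tau)

with ``a`` the annual intrinsic growth rate (1/yr), ``<Delta>`` the mean
displacement per generation (km) and ``tau`` the generation time (yr).
Arrival time at a cell is then the start date minus its least-cost distance
from the origin divided by ``v``. Distances run over a 16-direction lattice
graph (8 queen moves + 8 knight moves, reducing the directional bias of
plain queen connectivity) with edge weights equal to the Euclidean
centre-to-centre length times the mean friction of the two endpoints.
Biome-dependent friction implements the hypothesis that non-forest biomes
delayed the expansion: forest keeps friction 1, other biomes are costlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .landscape import BiomeRaster, GridGeometry

__all__ = [
    "FrontSpeedParams",
    "CostSurface",
    "ArrivalSurface",
    "KNIGHT_MOVES",
    "front_speed",
    "build_cost_surface",
    "least_cost_distance",
    "ebm_arrival",
]

# 16-direction connectivity: 8 queen steps plus 8 chess-knight steps.
KNIGHT_MOVES: tuple[tuple[int, int], ...] = tuple(
    (dr, dc)
    for dr in range(-2, 3)
    for dc in range(-2, 3)
    if (dr, dc) != (0, 0)
    and (max(abs(dr), abs(dc)) == 1 or {abs(dr), abs(dc)} == {1, 2})
)


@dataclass(frozen=True)
class FrontSpeedParams:
    """Demographic parameters of the wave of advance.

    Defaults are the study's baseline: 2.5%/yr growth, 50 km displacement
    per generation, 30-yr generations.
    """

    a: float = 0.025  # annual intrinsic growth rate, 1/yr
    mean_displacement: float = 50.0  # <Delta>, km per generation
    generation_time: float = 30.0  # tau, years

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("growth rate a must be non-negative")
        if self.mean_displacement <= 0:
            raise ValueError("mean displacement must be positive")
        if self.generation_time <= 0:
            raise ValueError("generation time must be positive")

    @property
    def diffusion_coefficient(self) -> float:
        """D = <Delta>^2 / (4 tau), km^2/yr."""
        return self.mean_displacement**2 / (4.0 * self.generation_time)


@dataclass(frozen=True, eq=False)
class CostSurface:
    """Per-cell friction multipliers (>= 1 on land; NaN marks impassable)."""

    geometry: GridGeometry
    friction: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        friction = np.asarray(self.friction, dtype=float)
        if friction.shape != self.geometry.shape:
            raise ValueError("friction shape does not match geometry")
        if np.any(friction[~np.isnan(friction)] < 1.0):
            raise ValueError("friction must be >= 1 on passable cells")
        object.__setattr__(self, "friction", friction)

    @property
    def passable(self) -> np.ndarray:
        return ~np.isnan(self.friction)


@dataclass(eq=False)
class ArrivalSurface:
    """First-settlement date per cell, years BP; NaN marks unreached cells.

    Unreached cells are explicit — they are never assigned a placeholder
    date here (clamping to the simulation end is an evaluation policy).
    """

    geometry: GridGeometry
    arrival: np.ndarray
    origin: tuple[int, int]
    start: float
    end: float

    def __post_init__(self) -> None:
        self.arrival = np.asarray(self.arrival, dtype=float)
        if self.arrival.shape != self.geometry.shape:
            raise ValueError("arrival shape does not match geometry")

    @property
    def reached(self) -> np.ndarray:
        return ~np.isnan(self.arrival)


def front_speed(params: FrontSpeedParams) -> float:
    """Asymptotic front speed (km/yr) of the time-delayed Fisher wave."""
    a, tau = params.a, params.generation_time
    d = params.diffusion_coefficient
    return 2.0 * math.sqrt(a * d) / (1.0 + a * tau / 2.0)


def build_cost_surface(raster: BiomeRaster, cost_map: dict) -> CostSurface:
    """Friction surface from a biome -> relative-cost mapping.

    Every biome code present on land must be mapped; nodata cells become
    impassable. Forest friction 1 with costlier non-forest biomes encodes
    the forest-corridor hypothesis; an all-ones map is the null surface.
    """
    land = raster.land_mask
    present = set(np.unique(raster.codes[land]).tolist())
    missing = sorted(present - set(cost_map))
    if missing:
        raise KeyError(
            f"biome codes {missing} present in the raster are missing from "
            "the cost map"
        )
    bad = sorted(c for c in present if cost_map[c] < 1.0)
    if bad:
        raise ValueError(f"cost map assigns friction < 1 to codes {bad}")
    friction = np.full(raster.geometry.shape, np.nan)
    for code in present:
        friction[raster.codes == code] = float(cost_map[code])
    return CostSurface(geometry=raster.geometry, friction=friction)


def _move_graph(surface: CostSurface) -> csr_matrix:
    """Sparse weighted adjacency over the 16-direction move set."""
    n_rows, n_cols = surface.geometry.shape
    cell = surface.geometry.cell_size
    fric = surface.friction
    passable = surface.passable
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)

    rows, cols, weights = [], [], []
    for dr, dc in KNIGHT_MOVES:
        # slices of source cells whose (dr, dc) neighbour is in bounds
        src = (
            slice(max(0, -dr), n_rows - max(0, dr)),
            slice(max(0, -dc), n_cols - max(0, dc)),
        )
        dst = (
            slice(max(0, dr), n_rows - max(0, -dr)),
            slice(max(0, dc), n_cols - max(0, -dc)),
        )
        ok = passable[src] & passable[dst]
        length = cell * math.hypot(dr, dc)
        w = length * 0.5 * (fric[src] + fric[dst])
        rows.append(idx[src][ok])
        cols.append(idx[dst][ok])
        weights.append(w[ok])
    return csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_rows * n_cols, n_rows * n_cols),
    )


def least_cost_distance(
    surface: CostSurface, origin: tuple[int, int]
) -> np.ndarray:
    """Least-cost distance (km) from ``origin`` to every cell.

    Dijkstra shortest paths over the knight's-move graph; unreachable and
    impassable cells are ``inf``.
    """
    r0, c0 = origin
    if not surface.passable[r0, c0]:
        raise ValueError(f"origin cell {origin} is impassable")
    graph = _move_graph(surface)
    flat = int(np.ravel_multi_index((r0, c0), surface.geometry.shape))
    dist = dijkstra(graph, directed=False, indices=flat)
    return dist.reshape(surface.geometry.shape)


def ebm_arrival(
    surface: CostSurface,
    origin: tuple[int, int],
    speed: float,
    start: float,
    end: float,
) -> ArrivalSurface:
    """Arrival surface: start date minus least-cost distance over speed.

    Cells whose implied arrival postdates ``end`` (the simulated horizon)
    and unreachable cells are flagged unreached (NaN).
    """
    if speed <= 0:
        raise ValueError("front speed must be positive")
    if start <= end:
        raise ValueError("start must be older (larger BP) than end")
    dist = least_cost_distance(surface, origin)
    arrival = start - dist / speed
    arrival[~np.isfinite(dist)] = np.nan
    arrival[arrival < end] = np.nan
    return ArrivalSurface(
        geometry=surface.geometry,
        arrival=arrival,
        origin=origin,
        start=start,
        end=end,
    )
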