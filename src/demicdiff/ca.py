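"""Cellular automaton of demic diffusion on a dynamic biome landscape.

Each generation (one time step of ``tau`` years, clock counting down in
years BP) every inhabited cell grows logistically toward the carrying
capacity K, then emits a density-dependent fraction of its population,
split equally among the available 8-neighbours (suitable biome, below K).
Where the habitable area is discontinuous, border cells of the forest whose
whole neighbourhood is blocked may "leapfrog" up to a fixed radius
(default 150 km) to the nearest habitable cells. When the millennial biome
slice in effect changes, populations stranded on newly unsuitable cells
relocate by the same rules or go extinct. The automaton is fully
deterministic: identical inputs give bit-identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ebm import ArrivalSurface
from .landscape import (
    GridGeometry,
    LandscapeSeries,
    biome_at,
    border_cells,
    suitability_mask,
)

__all__ = [
    "CAParams",
    "CAState",
    "CAResult",
    "logistic_growth",
    "emigration_rate",
    "disperse",
    "leapfrog_targets",
    "apply_environment",
    "run_ca",
]

_NEIGHBOURS_8 = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


@dataclass(frozen=True)
class CAParams:
    """Demographic and scheduling parameters of the automaton.

    ``carrying_capacity`` is a density (persons/km^2, default 1, i.e. 2500
    persons in a 50-km cell); ``emigration_rate_at_k`` is the fraction of a
    saturated cell that emigrates per generation (default 0.30) and
    ``emigration_shape`` the exponent of its density dependence (1 =
    linear). ``leapfrog_radius`` caps long-distance jumps (km).
    ``min_viable_density`` (persons per cell) optionally suppresses the
    recording of arrivals from infinitesimal trickles; the default 0 means
    any positive population settles a cell.
    """

    carrying_capacity: float = 1.0  # K, persons/km^2
    a: float = 0.025  # annual growth rate, 1/yr
    emigration_rate_at_k: float = 0.30  # epsilon, per generation
    emigration_shape: float = 1.0  # gamma
    generation_time: float = 30.0  # tau, years
    leapfrog_radius: float = 150.0  # km
    suitable_codes: frozenset[int] = frozenset({1})
    start: float = 5000.0  # years BP
    end: float = 500.0  # years BP
    min_viable_density: float = 0.0  # persons per cell

    def __post_init__(self) -> None:
        if not 0.0 <= self.emigration_rate_at_k <= 1.0:
            raise ValueError("emigration rate must be in [0, 1]")
        if self.emigration_shape <= 0:
            raise ValueError("emigration shape gamma must be positive")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying capacity must be positive")
        if self.generation_time <= 0:
            raise ValueError("generation time must be positive")
        if self.start <= self.end:
            raise ValueError("start must be older (larger BP) than end")
        object.__setattr__(
            self, "suitable_codes", frozenset(self.suitable_codes)
        )

    def cell_capacity(self, geometry: GridGeometry) -> float:
        """K expressed in persons per cell of the given grid."""
        return self.carrying_capacity * geometry.cell_size**2


@dataclass(eq=False)
class CAState:
    """Mutable per-generation state of the automaton."""

    geometry: GridGeometry
    population: np.ndarray  # persons per cell
    arrival: np.ndarray  # years BP, NaN = never settled
    current_date: float  # years BP
    suitable: np.ndarray  # current habitability mask
    border: np.ndarray = field(default=None)  # border cells of `suitable`

    def __post_init__(self) -> None:
        if self.border is None:
            self.border = border_cells(self.suitable)

    def copy(self) -> "CAState":
        return CAState(
            geometry=self.geometry,
            population=self.population.copy(),
            arrival=self.arrival.copy(),
            current_date=self.current_date,
            suitable=self.suitable.copy(),
            border=self.border.copy(),
        )


@dataclass(eq=False)
class CAResult:
    """Outcome of a run: arrival surface plus the population trajectory."""

    arrival: ArrivalSurface
    population: np.ndarray  # final per-cell population
    trajectory: pd.DataFrame  # one row per generation
    params: CAParams


def logistic_growth(
    n0: float | np.ndarray, k: float, a: float, tau: float
) -> float | np.ndarray:
    """Population after one generation of logistic growth.

    Closed-form solution of dN/dt = a N (1 - N/K) over ``tau`` years:
    ``K N0 / ((K - N0) e^{-a tau} + N0)``. 0 and K are exact fixed points;
    populations above K decay back toward K.
    """
    n0 = np.asarray(n0, dtype=float)
    out = np.where(
        n0 > 0, k * n0 / ((k - n0) * np.exp(-a * tau) + n0), 0.0
    )
    return float(out) if out.ndim == 0 else out


def emigration_rate(
    n: float | np.ndarray, k: float, eps: float, gamma: float
) -> float | np.ndarray:
    """Density-dependent emigration fraction eps * (N/K)^gamma, capped at 1."""
    n = np.asarray(n, dtype=float)
    out = np.minimum(eps * (n / k) ** gamma, 1.0)
    return float(out) if out.ndim == 0 else out


def _ring_offsets(radius_km: float, cell_size: float) -> np.ndarray:
    """Leapfrog offsets: beyond the 8-neighbourhood, centre distance <= radius."""
    reach = int(radius_km // cell_size)
    offs = [
        (dr, dc)
        for dr in range(-reach, reach + 1)
        for dc in range(-reach, reach + 1)
        if max(abs(dr), abs(dc)) > 1
        and cell_size * np.hypot(dr, dc) <= radius_km
    ]
    return np.array(offs, dtype=int) if offs else np.empty((0, 2), dtype=int)


def _candidate_targets(
    cell: tuple[int, int],
    offsets,
    available: np.ndarray,
) -> list[tuple[int, int]]:
    r, c = cell
    n_rows, n_cols = available.shape
    out = []
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        if 0 <= rr < n_rows and 0 <= cc < n_cols and available[rr, cc]:
            out.append((rr, cc))
    return out


def leapfrog_targets(
    state: CAState, cell: tuple[int, int], params: CAParams
) -> set[tuple[int, int]]:
    """Long-jump destinations for a blocked forest-border cell.

    Non-empty only when (i) ``cell`` sits on the border of the habitable
    area and (ii) none of its 8 neighbours can receive migrants. Returns
    every suitable, unsaturated cell within ``leapfrog_radius`` of the cell
    centre, excluding the 8-neighbourhood.
    """
    if not state.border[cell]:
        return set()
    k_cell = params.cell_capacity(state.geometry)
    available = state.suitable & (state.population < k_cell)
    if _candidate_targets(cell, _NEIGHBOURS_8, available):
        return set()
    ring = _ring_offsets(params.leapfrog_radius, state.geometry.cell_size)
    return set(_candidate_targets(cell, ring, available))


def disperse(state: CAState, params: CAParams) -> CAState:
    """One synchronous dispersal step.

    Every inhabited cell emits ``eps_t * N`` migrants, split equally over
    its available 8-neighbours; blocked border cells fall back to leapfrog
    targets; cells with no target anywhere keep their migrants (growth then
    saturates them at K). Total population is conserved exactly. Cells
    settled for the first time record the current date as their arrival.
    """
    new = state.copy()
    pop = state.population
    k_cell = params.cell_capacity(state.geometry)
    eps_t = emigration_rate(
        pop, k_cell, params.emigration_rate_at_k, params.emigration_shape
    )
    migrants = np.where(pop > 0, eps_t * pop, 0.0)
    # an inhabited cell's migrant flow eps*(N/K)^g*N is positive whenever
    # N > 0, even where the computed double underflows to zero at the far
    # tip of the front; settlement is therefore decided on this exact
    # predicate, not on the floating-point flow
    emits = (pop > 0) & (params.emigration_rate_at_k > 0)

    available = state.suitable & (pop < k_cell)
    # per-cell count of available 8-neighbours, vectorized by shifting
    n_rows, n_cols = pop.shape
    counts = np.zeros_like(pop, dtype=int)
    inflow = np.zeros_like(pop)
    settled = np.zeros_like(pop, dtype=bool)
    for dr, dc in _NEIGHBOURS_8:
        src = (
            slice(max(0, -dr), n_rows - max(0, dr)),
            slice(max(0, -dc), n_cols - max(0, dc)),
        )
        dst = (
            slice(max(0, dr), n_rows - max(0, -dr)),
            slice(max(0, dc), n_cols - max(0, -dc)),
        )
        counts[src] += available[dst]
    share = np.where(counts > 0, migrants / np.maximum(counts, 1), 0.0)
    for dr, dc in _NEIGHBOURS_8:
        src = (
            slice(max(0, -dr), n_rows - max(0, dr)),
            slice(max(0, -dc), n_cols - max(0, dc)),
        )
        dst = (
            slice(max(0, dr), n_rows - max(0, -dr)),
            slice(max(0, dc), n_cols - max(0, -dc)),
        )
        inflow[dst] += np.where(available[dst], share[src], 0.0)
        settled[dst] |= available[dst] & emits[src]
    dispatched = np.where(counts > 0, migrants, 0.0)

    # blocked cells: try leapfrogging from forest borders (deterministic
    # row-major order; flows are computed from the pre-step state)
    blocked = np.argwhere(emits & (counts == 0) & state.border)
    ring = _ring_offsets(params.leapfrog_radius, state.geometry.cell_size)
    for r, c in blocked:
        targets = _candidate_targets((int(r), int(c)), ring, available)
        if not targets:
            continue
        share_lf = migrants[r, c] / len(targets)
        for rr, cc in targets:
            inflow[rr, cc] += share_lf
            settled[rr, cc] = True
        dispatched[r, c] = migrants[r, c]

    new.population = pop - dispatched + inflow
    _record_settlement(new, settled, params)
    return new


def _record_settlement(
    state: CAState, settled: np.ndarray, params: CAParams
) -> None:
    """Record arrivals and keep colonized cells strictly inhabited.

    With the default ``min_viable_density`` of 0 any cell that received a
    (mathematically) positive flow is colonized; seeds whose computed
    inflow underflowed to zero are floored at the smallest positive double
    so "inhabited" (population > 0) stays consistent with the recorded
    arrival. A positive ``min_viable_density`` instead demands the actual
    received density, suppressing infinitesimal colonization.
    """
    if params.min_viable_density > 0:
        newly = (
            (state.population > params.min_viable_density)
            & np.isnan(state.arrival)
        )
    else:
        underflowed = settled & (state.population <= 0.0)
        state.population[underflowed] = np.nextafter(0.0, 1.0)
        newly = settled & np.isnan(state.arrival)
    state.arrival[newly] = state.current_date


def apply_environment(
    state: CAState, new_mask: np.ndarray, params: CAParams
) -> tuple[CAState, float]:
    """Switch to a new habitability mask, relocating stranded populations.

    Populations on cells that turn unsuitable move, whole, to available
    8-neighbours under the new mask (equal split), falling back to leapfrog
    targets; with no refuge anywhere within reach the population goes
    extinct. Arrival records are never erased. Returns the updated state
    and the total population lost to extinction.
    """
    if new_mask.shape != state.suitable.shape:
        raise ValueError("new mask shape does not match the state geometry")
    new = state.copy()
    new.suitable = new_mask.copy()
    new.border = border_cells(new_mask)
    k_cell = params.cell_capacity(state.geometry)

    stranded = np.argwhere((state.population > 0) & ~new_mask)
    if stranded.size == 0:
        return new, 0.0
    # synchronous: availability judged on the pre-relocation populations
    available = new_mask & (state.population < k_cell)
    ring = _ring_offsets(params.leapfrog_radius, state.geometry.cell_size)
    inflow = np.zeros_like(state.population)
    settled = np.zeros_like(state.population, dtype=bool)
    extinct = 0.0
    for r, c in stranded:
        cell = (int(r), int(c))
        targets = _candidate_targets(cell, _NEIGHBOURS_8, available)
        if not targets:
            targets = _candidate_targets(cell, ring, available)
        amount = state.population[r, c]
        new.population[r, c] = 0.0
        if targets:
            for rr, cc in targets:
                inflow[rr, cc] += amount / len(targets)
                settled[rr, cc] = True
        else:
            extinct += amount
    new.population += inflow
    _record_settlement(new, settled, params)
    return new, extinct


def run_ca(
    series: LandscapeSeries,
    params: CAParams,
    origin: tuple[int, int],
) -> CAResult:
    """Run the automaton from a single settled cell to the end date.

    The origin starts at K at the start date and disperses from the first
    generation on. Each generation: (1) if the nearest biome slice changed,
    apply the environmental update; (2) logistic growth on every inhabited
    cell; (3) synchronous dispersal. Returns the arrival surface and a
    per-generation trajectory (date, inhabited cells, total population,
    extinctions).
    """
    geom = series.geometry
    k_cell = params.cell_capacity(geom)
    raster = biome_at(series, params.start)
    suitable = suitability_mask(raster, params.suitable_codes)
    if not suitable[origin]:
        raise ValueError(
            f"origin {origin} is not on a suitable biome at "
            f"{params.start} BP"
        )

    pop = np.zeros(geom.shape)
    arrival = np.full(geom.shape, np.nan)
    pop[origin] = k_cell
    arrival[origin] = params.start
    state = CAState(
        geometry=geom,
        population=pop,
        arrival=arrival,
        current_date=params.start,
        suitable=suitable,
    )
    current_slice = raster.slice_date

    rows = []
    n_generations = int(
        np.floor((params.start - params.end) / params.generation_time)
    )
    for step in range(1, n_generations + 1):
        date = params.start - step * params.generation_time
        state.current_date = date
        extinct = 0.0
        raster = biome_at(series, date)
        if raster.slice_date != current_slice:
            mask = suitability_mask(raster, params.suitable_codes)
            state, extinct = apply_environment(state, mask, params)
            current_slice = raster.slice_date
        state.population = np.where(
            state.population > 0,
            logistic_growth(
                state.population, k_cell, params.a, params.generation_time
            ),
            0.0,
        )
        state = disperse(state, params)
        rows.append(
            {
                "date_bp": date,
                "n_inhabited": int(np.count_nonzero(state.population > 0)),
                "total_population": float(state.population.sum()),
                "extinct_population": extinct,
            }
        )

    surface = ArrivalSurface(
        geometry=geom,
        arrival=state.arrival,
        origin=origin,
        start=params.start,
        end=params.end,
    )
    return CAResult(
        arrival=surface,
        population=state.population,
        trajectory=pd.DataFrame(rows),
        params=params,
    )
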