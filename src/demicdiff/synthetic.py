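"""Synthetic landscapes and date tables with the structure the models assume.

Real inputs — millennial palaeovegetation reconstructions and a compiled
radiocarbon database — are large external datasets. This module builds
small stand-ins with the same statistical structure: two forest blocks
joined by a corridor that opens at a configurable slice (emulating
climate-driven forest expansion opening dispersal corridors), and date
tables drawn from a simulated arrival surface with a non-negative
"later-than-first-arrival" lag plus measurement noise. Everything is
seed-deterministic so fixtures regenerate bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ca import CAParams, CAResult, run_ca
from .ebm import ArrivalSurface
from .landscape import BiomeRaster, GridGeometry, LandscapeSeries

__all__ = [
    "FOREST",
    "SAVANNA",
    "CorridorScenario",
    "DateGenConfig",
    "make_corridor_series",
    "make_dates",
    "reference_experiment",
    "ReferenceExperiment",
]

FOREST = 1  # tropical moist forest
SAVANNA = 2  # open (non-forest) biome


def _zigzag_corridor() -> tuple[tuple[int, int], ...]:
    """Winding 1-cell corridor through the default gap (cols 16-23).

    Two vertical legs five columns apart (beyond the 150-km leapfrog
    reach), giving a ~21-generation traversal while the straight-line gap
    stays eight columns wide.
    """
    path = [(20, 16), (20, 17)]
    path += [(r, 17) for r in range(19, 11, -1)]  # up col 17, rows 19..12
    path += [(12, c) for c in range(18, 23)]  # east along row 12
    path += [(r, 22) for r in range(13, 21)]  # down col 22, rows 13..20
    path += [(20, 23)]
    return tuple(path)


@dataclass(frozen=True)
class CorridorScenario:
    """Two forest blocks joined by a corridor opening at a given slice.

    Blocks are column ranges spanning all rows; the corridor is an explicit
    cell path through the non-forest gap. Before ``corridor_open_date`` the
    forest mask has two 8-connected components; from the slice nearest
    (>=) that date onward the corridor is forest and the blocks connect.
    """

    n_rows: int = 40
    n_cols: int = 40
    cell_size: float = 50.0
    block_a_cols: tuple[int, int] = (0, 15)  # inclusive column range
    block_b_cols: tuple[int, int] = (24, 39)
    corridor_cells: tuple[tuple[int, int], ...] = field(
        default_factory=_zigzag_corridor
    )
    corridor_open_date: float = 3000.0  # years BP
    forest_code: int = FOREST
    background_code: int = SAVANNA
    slice_dates: tuple[float, ...] = (5000.0, 4000.0, 3000.0, 2000.0, 1000.0)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size=self.cell_size,
            x_origin=self.cell_size / 2.0,
            y_origin=self.cell_size / 2.0,
        )


@dataclass(frozen=True)
class DateGenConfig:
    """Sampling model for synthetic dated sites.

    Observed age = simulated arrival − Exponential(lag_mean) +
    Normal(0, noise_sd): dates lag the true first arrival (archaeological
    visibility builds up after colonization) and carry symmetric
    measurement scatter.
    """

    n_sites: int = 80
    lag_mean: float = 200.0  # years
    noise_sd: float = 100.0  # years
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag_mean < 0 or self.noise_sd < 0:
            raise ValueError("lag_mean and noise_sd must be non-negative")
        if self.n_sites < 1:
            raise ValueError("n_sites must be at least 1")


def make_corridor_series(scenario: CorridorScenario) -> LandscapeSeries:
    """Build the biome raster stack of a corridor scenario."""
    dates = sorted(scenario.slice_dates, reverse=True)
    if not (min(dates) <= scenario.corridor_open_date <= max(dates)):
        raise ValueError(
            f"corridor_open_date {scenario.corridor_open_date} BP outside "
            f"the slice range [{min(dates)}, {max(dates)}] BP"
        )
    geom = scenario.geometry
    base = np.full(geom.shape, scenario.background_code, dtype=int)
    for lo, hi in (scenario.block_a_cols, scenario.block_b_cols):
        base[:, lo : hi + 1] = scenario.forest_code

    slices = {}
    for d in dates:
        codes = base.copy()
        if d <= scenario.corridor_open_date:
            for r, c in scenario.corridor_cells:
                codes[r, c] = scenario.forest_code
        slices[d] = BiomeRaster(geometry=geom, codes=codes)
    return LandscapeSeries(slices)


def make_dates(
    arrival: ArrivalSurface, cfg: DateGenConfig
) -> pd.DataFrame:
    """Draw a synthetic dated-site table from an arrival surface.

    Samples ``n_sites`` reached cells without replacement; each site sits
    at its cell centre and its observed median age is the simulated arrival
    minus an exponential lag plus Gaussian noise, truncated to stay within
    (0, start]. Identical seeds give identical tables.
    """
    reached = np.argwhere(arrival.reached)
    if len(reached) < cfg.n_sites:
        raise ValueError(
            f"arrival surface has {len(reached)} reached cells, fewer than "
            f"the {cfg.n_sites} requested sites"
        )
    rng = np.random.default_rng(cfg.seed)
    pick = rng.choice(len(reached), size=cfg.n_sites, replace=False)
    rows = []
    for i, j in enumerate(sorted(pick.tolist())):
        r, c = (int(v) for v in reached[j])
        x, y = arrival.geometry.cell_center(r, c)
        true_bp = float(arrival.arrival[r, c])
        lag = rng.exponential(cfg.lag_mean) if cfg.lag_mean > 0 else 0.0
        noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
        obs = np.clip(true_bp - lag + noise, 1.0, arrival.start)
        rows.append(
            {
                "site_id": f"syn{i:04d}",
                "x": x,
                "y": y,
                "med_cal_bp": float(obs),
            }
        )
    return pd.DataFrame(rows)


@dataclass(eq=False)
class ReferenceExperiment:
    """Bundled standard fixture: landscape, reference run, and dates."""

    scenario: CorridorScenario
    series: LandscapeSeries
    origin: tuple[int, int]
    params: CAParams
    result: CAResult
    dates: pd.DataFrame
    date_config: DateGenConfig


def reference_experiment(seed: int = 0) -> ReferenceExperiment:
    """Run the standard corridor experiment used as the repo's test fixture.

    A 40x40 corridor landscape is simulated with the cellular automaton
    under forest-restricted (alternative-hypothesis) rules from 5000 to
    500 BP, and a dated-site table is drawn from the resulting arrival
    surface. Only the date sampling is stochastic; the seed controls it.
    """
    scenario = CorridorScenario()
    series = make_corridor_series(scenario)
    origin = (20, 8)  # mid-height of forest block A
    params = CAParams(suitable_codes=frozenset({scenario.forest_code}))
    result = run_ca(series, params, origin)
    cfg = DateGenConfig(seed=seed)
    dates = make_dates(result.arrival, cfg)
    return ReferenceExperiment(
        scenario=scenario,
        series=series,
        origin=origin,
        params=params,
        result=result,
        dates=dates,
        date_config=cfg,
    )
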