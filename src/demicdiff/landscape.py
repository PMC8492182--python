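"""Gridded world: equal-area raster geometry, categorical biomes, suitability.

The model world is a stack of categorical biome rasters (one per millennial
time slice) on a shared equal-area grid of square cells, following the
convention of palaeovegetation reconstructions used in demic-diffusion
studies: row 0 is the northernmost row, cells are addressed ``(row, col)``,
and projected coordinates refer to cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GridGeometry",
    "BiomeRaster",
    "LandscapeSeries",
    "biome_at",
    "suitability_mask",
    "border_cells",
]


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of an equal-area raster grid.

    ``x_origin``/``y_origin`` are the projected coordinates (km) of the
    *centre* of the lower-left cell, i.e. cell ``(n_rows - 1, 0)``.
    ``cell_size`` is the side of a square cell in km (default 50, the
    resolution of the millennial biome reconstructions).
    """

    n_rows: int
    n_cols: int
    cell_size: float = 50.0
    x_origin: float = 25.0
    y_origin: float = 25.0
    projection_tag: str = "albers-equal-area"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Projected (x, y) of a cell centre; row 0 is the northernmost row."""
        x = self.x_origin + col * self.cell_size
        y = self.y_origin + (self.n_rows - 1 - row) * self.cell_size
        return (x, y)

    def cell_containing(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) whose square footprint contains projected (x, y).

        Raises ``ValueError`` if the point falls outside the grid.
        """
        half = self.cell_size / 2.0
        col = int(np.floor((x - (self.x_origin - half)) / self.cell_size))
        row_from_bottom = int(
            np.floor((y - (self.y_origin - half)) / self.cell_size)
        )
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(
                f"point ({x}, {y}) falls outside the grid "
                f"({self.n_rows} x {self.n_cols} cells of {self.cell_size} km)"
            )
        return (row, col)


@dataclass(frozen=True, eq=False)
class BiomeRaster:
    """Categorical biome raster: integer code per cell, nodata for non-land."""

    geometry: GridGeometry
    codes: np.ndarray = field(repr=False)
    nodata_code: int = -9999
    slice_date: float | None = None  # years BP, set when part of a series

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        if codes.shape != self.geometry.shape:
            raise ValueError(
                f"codes shape {codes.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        object.__setattr__(self, "codes", codes)

    @property
    def land_mask(self) -> np.ndarray:
        return self.codes != self.nodata_code


class LandscapeSeries:
    """Time-indexed biome rasters on one shared grid.

    Slice dates are years BP in strictly decreasing order (oldest first),
    e.g. 5000, 4000, ..., 1000. Lookups are nearest-neighbour in time with
    ties toward the older slice; categorical biomes are never interpolated.
    """

    def __init__(self, slices: dict[float, BiomeRaster]):
        if not slices:
            raise ValueError("a landscape series needs at least one slice")
        dates = sorted(slices, reverse=True)
        geom = slices[dates[0]].geometry
        for d in dates:
            if slices[d].geometry != geom:
                raise ValueError(
                    f"slice {d} BP has a different grid geometry than "
                    f"slice {dates[0]} BP"
                )
        self._dates = np.array(dates, dtype=float)
        self._slices = {
            float(d): BiomeRaster(
                geometry=slices[d].geometry,
                codes=slices[d].codes,
                nodata_code=slices[d].nodata_code,
                slice_date=float(d),
            )
            for d in dates
        }

    @property
    def geometry(self) -> GridGeometry:
        return next(iter(self._slices.values())).geometry

    @property
    def slice_dates(self) -> np.ndarray:
        """Slice dates in years BP, descending."""
        return self._dates.copy()

    def __len__(self) -> int:
        return len(self._dates)

    def __getitem__(self, slice_date: float) -> BiomeRaster:
        return self._slices[float(slice_date)]

    def covered_range(self) -> tuple[float, float]:
        """(youngest, oldest) date covered, padded by half the end gaps.

        A single-slice series is constant in time and covers all dates.
        """
        if len(self._dates) == 1:
            return (-np.inf, np.inf)
        oldest, youngest = self._dates[0], self._dates[-1]
        old_gap = self._dates[0] - self._dates[1]
        young_gap = self._dates[-2] - self._dates[-1]
        return (youngest - young_gap / 2.0, oldest + old_gap / 2.0)


def biome_at(series: LandscapeSeries, date: float) -> BiomeRaster:
    """Biome raster in effect at ``date`` (years BP).

    Nearest slice in time; an exact tie between two slices resolves to the
    older one. Dates outside the covered range (slice span padded by half
    the end gaps) raise ``ValueError`` naming the range.
    """
    lo, hi = series.covered_range()
    if not (lo <= date <= hi):
        raise ValueError(
            f"date {date} BP outside the covered range "
            f"[{lo}, {hi}] BP of this landscape series"
        )
    dates = series.slice_dates
    dist = np.abs(dates - date)
    best = dist.min()
    # candidates within tie tolerance; dates are descending so [0] is oldest
    winner = dates[np.nonzero(dist == best)[0][0]]
    return series[winner]


def suitability_mask(raster: BiomeRaster, suitable_codes) -> np.ndarray:
    """Boolean mask of habitable cells: code in ``suitable_codes``, land only."""
    suitable_codes = set(suitable_codes)
    if not suitable_codes:
        raise ValueError("suitable_codes must be non-empty")
    mask = np.isin(raster.codes, list(suitable_codes))
    mask &= raster.land_mask
    return mask


def border_cells(mask: np.ndarray) -> np.ndarray:
    """Cells of ``mask`` adjacent (8-neighbourhood) to an unsuitable cell.

    Off-grid neighbours do not count: the map edge is a cropping artefact,
    not an ecological border, so an all-true mask has no border cells.
    """
    mask = np.asarray(mask, dtype=bool)
    # pad value True: outside-the-world neighbours never mark a border
    neighbourhood_min = ndimage.minimum_filter(
        mask, size=3, mode="constant", cval=True
    )
    return mask & ~neighbourhood_min
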