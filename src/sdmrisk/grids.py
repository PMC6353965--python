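"""Grid geometry and environmental raster stacks.

All rasters in a run live on one shared geographic grid (``GridSpec``):
cell-centre registration, row 0 is the northernmost row, values are plain
``float64`` arrays with ``NaN`` marking masked / no-data cells. A masked
cell is masked identically in every layer of a stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = ["GridSpec", "EnvStack", "ARC_MIN_2_5"]

#: 2.5 arc-minutes in decimal degrees, the working resolution.
ARC_MIN_2_5 = 2.5 / 60.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a geographic raster grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; at least 2 each.
    cell_size : float
        Cell edge length in decimal degrees (default 2.5 arc-min).
    origin_lon, origin_lat : float
        Longitude of the western edge and latitude of the *northern* edge
        of the grid (top-left corner).
    crs_id : str
        Geographic CRS identifier; informational only.
    """

    n_rows: int
    n_cols: int
    cell_size: float = ARC_MIN_2_5
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    crs_id: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def west(self) -> float:
        return self.origin_lon

    @property
    def east(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size

    @property
    def north(self) -> float:
        return self.origin_lat

    @property
    def south(self) -> float:
        return self.origin_lat - self.n_rows * self.cell_size

    def cell_lons(self) -> np.ndarray:
        """Cell-centre longitudes, west to east (length ``n_cols``)."""
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def cell_lats(self) -> np.ndarray:
        """Cell-centre latitudes, north to south (length ``n_rows``)."""
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing the given points."""
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.cell_size)
        return row.astype(int), col.astype(int)

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.cell_of(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def centre_of(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinates for row/column indices."""
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat


@dataclass
class EnvStack:
    """A named set of co-registered raster layers on one grid.

    ``layers`` maps layer name to a ``(n_rows, n_cols)`` float array; NaN
    marks no-data. ``static_flags`` marks layers (e.g. vegetation cover)
    assumed constant into the future. ``train_bounds`` holds the per-layer
    (min, max) observed over the calibration cells, used for clamping
    projections. ``clamped`` records that :func:`sdmrisk.predictors.clamp`
    has been applied.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    static_flags: dict[str, bool] = field(default_factory=dict)
    train_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    clamped: bool = False

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack must contain at least one layer")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}"
                )
            self.layers[name] = arr
        for name in self.layers:
            self.static_flags.setdefault(name, False)
        for name, (lo, hi) in self.train_bounds.items():
            if lo > hi:
                raise ValueError(f"train_bounds for {name!r}: min {lo} > max {hi}")
        self._unify_mask()

    # -- masking ---------------------------------------------------------
    def _unify_mask(self) -> None:
        """Propagate NaN so a masked cell is masked in every layer."""
        mask = np.zeros(self.grid.shape, dtype=bool)
        for arr in self.layers.values():
            mask |= np.isnan(arr)
        if mask.any():
            for arr in self.layers.values():
                arr[mask] = np.nan
        self._mask = mask

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where cells are no-data."""
        return self._mask

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def dynamic_names(self) -> list[str]:
        return [n for n in self.layers if not self.static_flags[n]]

    @property
    def static_names(self) -> list[str]:
        return [n for n in self.layers if self.static_flags[n]]

    def n_layers(self) -> int:
        return len(self.layers)

    # -- extraction ------------------------------------------------------
    def valid_cells(self) -> np.ndarray:
        """Flat indices (row-major) of unmasked cells."""
        return np.flatnonzero(~self._mask.ravel())

    def to_matrix(
        self, names: Iterable[str] | None = None, cells: np.ndarray | None = None
    ) -> np.ndarray:
        """Stack layer values into an ``(n_cells, n_layers)`` matrix.

        ``cells`` are flat row-major indices; default all unmasked cells.
        """
        names = list(names) if names is not None else self.layer_names
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        if cells is None:
            cells = self.valid_cells()
        return np.column_stack([self.layers[n].ravel()[cells] for n in names])

    def values_at(self, lon, lat, names: Iterable[str] | None = None) -> np.ndarray:
        """Layer values at point coordinates, shape ``(n_points, n_layers)``."""
        row, col = self.grid.cell_of(lon, lat)
        if np.any(~self.grid.contains(lon, lat)):
            raise ValueError("point(s) outside grid extent")
        flat = row * self.grid.n_cols + col
        names = list(names) if names is not None else self.layer_names
        return np.column_stack([self.layers[n].ravel()[flat] for n in names])

    # -- manipulation ----------------------------------------------------
    def copy(self) -> "EnvStack":
        return EnvStack(
            grid=self.grid,
            layers={n: a.copy() for n, a in self.layers.items()},
            static_flags=dict(self.static_flags),
            train_bounds=dict(self.train_bounds),
            clamped=self.clamped,
        )

    def subset(self, names: Iterable[str]) -> "EnvStack":
        names = list(names)
        return EnvStack(
            grid=self.grid,
            layers={n: self.layers[n].copy() for n in names},
            static_flags={n: self.static_flags[n] for n in names},
            train_bounds={n: self.train_bounds[n] for n in names if n in self.train_bounds},
            clamped=self.clamped,
        )


def check_same_grid(*stacks: EnvStack) -> GridSpec:
    """Require all stacks to share one GridSpec; return it."""
    grids = {s.grid for s in stacks}
    if len(grids) != 1:
        descr = "\n".join(repr(s.grid) for s in stacks)
        raise ValueError(f"stacks are not co-registered; grids:\n{descr}")
    return stacks[0].grid


def set_train_bounds(stack: EnvStack, cells: np.ndarray | None = None) -> EnvStack:
    """Record per-layer min/max over ``cells`` (flat indices) as training bounds."""
    out = stack.copy()
    if cells is None:
        cells = stack.valid_cells()
    for name, arr in out.layers.items():
        vals = arr.ravel()[cells]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"no unmasked calibration cells for layer {name!r}")
        out.train_bounds[name] = (float(vals.min()), float(vals.max()))
    return out
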