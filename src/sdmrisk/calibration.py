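"""Species-specific calibration regions, background points, CV blocks.

Model calibration is restricted to a buffered minimum convex polygon
(MCP) of the species occurrences — the buffer distance equals the mean
pairwise great-circle distance between the occurrence points — to avoid
contrasting presences against environments the species never encounters.
Species whose MCP covers more than half of the study area are calibrated
on the whole study area instead. 10,000 background points (or as many
cells as are available) are drawn uniformly over unmasked cells within
the region. Evaluation uses four spatial blocks formed by splitting the
occurrences at their median longitude and latitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon, box

from .grids import EnvStack, GridSpec
from .occurrences import EARTH_RADIUS_KM, OccurrenceSet, pairwise_haversine_km

__all__ = [
    "CalibrationRegion",
    "CVBlocks",
    "mean_pairwise_distance_km",
    "build_calibration_region",
    "make_blocks",
    "assign_quadrants",
]


# ---------------------------------------------------------------------------
# local azimuthal equidistant projection (km-true buffering without pyproj)
# ---------------------------------------------------------------------------

def _aeq_forward(lons, lats, lon0: float, lat0: float):
    """Project lon/lat (degrees) to azimuthal-equidistant x, y in km."""
    lam, phi = np.radians(lons), np.radians(lats)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 0, c / np.sin(c), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def _aeq_inverse(x, y, lon0: float, lat0: float):
    """Inverse azimuthal-equidistant: x, y in km back to lon/lat degrees."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    c = np.hypot(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.where(
            c > 0,
            np.arcsin(np.clip(cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / c, -1, 1)),
            phi0,
        )
        lam = np.where(
            c > 0,
            lam0 + np.arctan2(x * sin_c, c * np.cos(phi0) * cos_c - y * sin_c * np.sin(phi0)),
            lam0,
        )
    return np.degrees(lam), np.degrees(phi)


def _buffer_in_km(points_lonlat: np.ndarray, geom_builder, buffer_km: float) -> Polygon:
    """Buffer a geometry built from points by ``buffer_km`` true km.

    Projects to a local azimuthal-equidistant plane centred on the point
    centroid, buffers there, and re-projects the boundary.
    """
    lon0 = float(points_lonlat[:, 0].mean())
    lat0 = float(points_lonlat[:, 1].mean())
    x, y = _aeq_forward(points_lonlat[:, 0], points_lonlat[:, 1], lon0, lat0)
    geom = geom_builder(np.column_stack([x, y]))
    buffered = geom.buffer(buffer_km, quad_segs=32)
    bx, by = np.array(buffered.exterior.coords).T
    blon, blat = _aeq_inverse(bx, by, lon0, lat0)
    return Polygon(np.column_stack([blon, blat]))


def mean_pairwise_distance_km(lons, lats) -> float:
    """Mean over all unordered point pairs of great-circle distance."""
    n = len(lons)
    if n < 2:
        raise ValueError("need at least 2 points")
    d = pairwise_haversine_km(lons, lats)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


# ---------------------------------------------------------------------------
# calibration region
# ---------------------------------------------------------------------------

@dataclass
class CalibrationRegion:
    """Model-fitting domain for one species.

    ``polygon`` is the buffered MCP (or the full study extent) in
    geographic coordinates; ``background`` holds sampled background point
    coordinates at cell centres; ``cells`` their flat grid indices;
    ``area_fraction`` the unmasked-cell fraction of the study area the
    buffered MCP covered.
    """

    polygon: Polygon
    buffer_km: float
    used_full_area: bool
    background: pd.DataFrame
    cells: np.ndarray
    area_fraction: float


def build_calibration_region(
    occ: OccurrenceSet,
    stack: EnvStack,
    n_background: int = 10_000,
    seed: int = 0,
    full_area_fraction: float = 0.5,
) -> CalibrationRegion:
    """Buffered-MCP calibration region with uniform background sample.

    The buffer distance is the mean pairwise great-circle distance between
    the occurrences. If the buffered MCP covers more than
    ``full_area_fraction`` of the study area (by count of unmasked cells),
    the whole study area is used instead. Background points are drawn
    uniformly, without replacement, at unmasked cell centres inside the
    region; if fewer cells are available than requested, all are taken
    with a warning.
    """
    grid = stack.grid
    pts = np.column_stack([occ.lons, occ.lats])
    n = len(occ)
    if n < 1:
        raise ValueError("cannot build a calibration region without occurrences")

    if n >= 2:
        buffer_km = mean_pairwise_distance_km(occ.lons, occ.lats)
    else:
        buffer_km = grid.cell_size * 111.19  # lone record: one-cell-scale disk

    # MCP = convex hull; with < 3 usable points (or collinear points) the
    # hull degenerates to a point/segment and buffering it yields the union
    # of buffer disks / a corridor, which is the documented fallback.
    polygon = _buffer_in_km(
        pts, lambda xy: MultiPoint(list(map(tuple, xy))).convex_hull, buffer_km
    )

    # eligibility: unmasked cell centres inside the polygon
    valid = stack.valid_cells()
    rows, cols = np.divmod(valid, grid.n_cols)
    lon_c, lat_c = grid.centre_of(rows, cols)
    inside = shapely.contains_xy(polygon, lon_c, lat_c)
    area_fraction = float(inside.sum()) / float(valid.size)

    used_full_area = area_fraction > full_area_fraction
    if used_full_area:
        polygon = box(grid.west, grid.south, grid.east, grid.north)
        eligible = valid
    else:
        eligible = valid[inside]

    # occurrences must fall inside the region; tiny tolerance at the rim
    occ_inside = shapely.contains_xy(polygon.buffer(1e-9), occ.lons, occ.lats)
    if not occ_inside.all():
        raise RuntimeError("calibration polygon does not contain all occurrences")

    rng = np.random.default_rng(seed)
    if eligible.size < n_background:
        warnings.warn(
            f"only {eligible.size} background cells available in the calibration "
            f"region (requested {n_background}); using all of them"
        )
        chosen = eligible.copy()
    else:
        chosen = rng.choice(eligible, size=n_background, replace=False)
    brow, bcol = np.divmod(chosen, grid.n_cols)
    blon, blat = grid.centre_of(brow, bcol)
    background = pd.DataFrame({"lon": blon, "lat": blat})

    return CalibrationRegion(
        polygon=polygon,
        buffer_km=float(buffer_km),
        used_full_area=used_full_area,
        background=background,
        cells=np.sort(chosen),
        area_fraction=area_fraction,
    )


# ---------------------------------------------------------------------------
# spatial cross-validation blocks
# ---------------------------------------------------------------------------

@dataclass
class CVBlocks:
    """Assignment of records to four spatial quadrant blocks.

    Blocks are formed by splitting at the occurrence median longitude and
    latitude; points exactly on a median go to the lower-indexed (west /
    south) block. ``med_lon`` / ``med_lat`` are kept so other point sets
    (background) can be split by the same rule.
    """

    assignment: np.ndarray
    med_lon: float
    med_lat: float
    scheme: str = "lon-lat-quadrant"

    @property
    def block_ids(self) -> np.ndarray:
        return np.unique(self.assignment)


def assign_quadrants(lons, lats, med_lon: float, med_lat: float) -> np.ndarray:
    """Quadrant block ids in {1..4}: 1=SW, 2=SE, 3=NW, 4=NE (ties go low)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return (1 + (lons > med_lon).astype(int) + 2 * (lats > med_lat).astype(int)).astype(int)


def make_blocks(occ: OccurrenceSet) -> CVBlocks:
    """Split occurrences into four spatial blocks at their coordinate medians."""
    lons, lats = occ.lons, occ.lats
    n = len(occ)
    if n == 0:
        raise ValueError("no records to block")
    if np.all(lons == lons[0]) and np.all(lats == lats[0]):
        raise ValueError("all records at one coordinate: spatial blocking degenerate")
    if n < 8:
        warnings.warn(f"only {n} records: 4-block spatial CV will be weak")
    med_lon = float(np.median(lons))
    med_lat = float(np.median(lats))
    assignment = assign_quadrants(lons, lats, med_lon, med_lat)
    n_blocks = np.unique(assignment).size
    if n >= 4 and n_blocks < 4:
        warnings.warn(f"only {n_blocks} non-empty spatial blocks (coordinate ties)")
    return CVBlocks(assignment=assignment, med_lon=med_lon, med_lat=med_lat)
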