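"""Occurrence record cleaning and dispersal-group spatial thinning.

Raw multi-source occurrence compilations carry duplicated records and
strong spatial sampling bias. Cleaning restricts records to a year window
and keeps at most one record per grid cell; thinning then subsets the
records so that no two retained points lie closer than a minimum
great-circle distance, chosen by dispersal group: 5 km for small, 10 km
for volant and 20 km for large mammals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec

__all__ = [
    "EARTH_RADIUS_KM",
    "GROUP_THIN_KM",
    "OccurrenceSet",
    "haversine_km",
    "pairwise_haversine_km",
    "clean_records",
    "spatial_thin",
]

EARTH_RADIUS_KM = 6371.0088

#: Spatial-thinning distance (km) per dispersal group.
GROUP_THIN_KM = {"small": 5.0, "volant": 10.0, "large": 20.0}


@dataclass
class OccurrenceSet:
    """One species' cleaned point records.

    ``records`` has columns lon, lat, year, source. ``group`` tags the
    dispersal group and implies the default thinning distance;
    ``thin_distance_km`` records the distance actually applied (None before
    thinning).
    """

    species_id: str
    records: pd.DataFrame
    group: str | None = None
    thin_distance_km: float | None = None
    log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lons(self) -> np.ndarray:
        return self.records["lon"].to_numpy()

    @property
    def lats(self) -> np.ndarray:
        return self.records["lat"].to_numpy()

    @property
    def default_thin_km(self) -> float:
        if self.group is None:
            raise ValueError("occurrence set has no dispersal group tag")
        try:
            return GROUP_THIN_KM[self.group]
        except KeyError:
            raise ValueError(f"unknown dispersal group {self.group!r}") from None


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lons, lats) -> np.ndarray:
    """Square matrix of pairwise great-circle distances."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def clean_records(
    raw: pd.DataFrame,
    grid: GridSpec,
    year_min: int = 1960,
    year_max: int = 2005,
    species_id: str | None = None,
    group: str | None = None,
) -> OccurrenceSet:
    """Clean raw records: coordinate/year validation, year window, cell dedup.

    Keeps at most one record per grid cell (first in stable input order).
    Removal counts per reason are recorded in the returned set's ``log``.
    """
    raw = raw.reset_index(drop=True)
    if species_id is None:
        species_id = str(raw["species"].iloc[0]) if len(raw) and "species" in raw else "unknown"
    log = {"n_input": len(raw)}

    lon = pd.to_numeric(raw.get("lon"), errors="coerce")
    lat = pd.to_numeric(raw.get("lat"), errors="coerce")
    year = pd.to_numeric(raw.get("year"), errors="coerce")
    parseable = ~(lon.isna() | lat.isna() | year.isna())
    log["n_unparseable"] = int((~parseable).sum())
    if log["n_unparseable"]:
        warnings.warn(f"{species_id}: skipped {log['n_unparseable']} unparseable rows")

    in_bounds = parseable & lon.between(-180, 180) & lat.between(-90, 90)
    log["n_out_of_bounds"] = int((parseable & ~in_bounds).sum())

    in_window = in_bounds & year.between(year_min, year_max)
    log["n_outside_year_window"] = int((in_bounds & ~in_window).sum())

    kept = raw[in_window].copy()
    kept["lon"] = lon[in_window]
    kept["lat"] = lat[in_window]
    kept["year"] = year[in_window].astype(int)
    if "source" not in kept.columns:
        kept["source"] = ""

    row, col = grid.cell_of(kept["lon"].to_numpy(), kept["lat"].to_numpy())
    cell_key = row * grid.n_cols + col
    first = ~pd.Series(cell_key, index=kept.index).duplicated()
    log["n_cell_duplicates"] = int((~first).sum())
    kept = kept[first]

    log["n_kept"] = len(kept)
    records = kept[["lon", "lat", "year", "source"]].reset_index(drop=True)
    return OccurrenceSet(species_id=species_id, records=records, group=group, log=log)


def _thin_once(adj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One randomized thinning pass: repeatedly drop a random member of the
    currently most-conflicted set until no conflicts remain."""
    alive = np.ones(adj.shape[0], dtype=bool)
    deg = adj.sum(axis=1)
    while True:
        max_deg = deg[alive].max(initial=0)
        if max_deg == 0:
            return alive
        candidates = np.flatnonzero(alive & (deg == max_deg))
        victim = rng.choice(candidates)
        alive[victim] = False
        deg[adj[victim]] -= 1
        deg[victim] = 0


def spatial_thin(
    occ: OccurrenceSet,
    min_dist_km: float | None = None,
    n_tries: int = 100,
    seed: int = 0,
) -> OccurrenceSet:
    """Subset records so every pairwise great-circle distance >= min_dist_km.

    A randomized removal heuristic (drop a random maximally-conflicted
    point until conflict-free) is repeated ``n_tries`` times and the
    largest surviving subset is kept — the search target is the highest
    achievable number of records satisfying the distance constraint.
    Deterministic for a given seed; the output is always a subset of the
    input and the constraint is asserted on it.
    """
    if min_dist_km is None:
        min_dist_km = occ.default_thin_km
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be positive")
    n = len(occ)
    if n <= 1:
        return OccurrenceSet(occ.species_id, occ.records.copy(), occ.group, min_dist_km, dict(occ.log))

    dist = pairwise_haversine_km(occ.lons, occ.lats)
    adj = dist < min_dist_km
    np.fill_diagonal(adj, False)

    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    if not adj.any():
        best = np.ones(n, dtype=bool)
    else:
        for _ in range(n_tries):
            alive = _thin_once(adj, rng)
            if best is None or alive.sum() > best.sum():
                best = alive

    sub = dist[np.ix_(best, best)]
    np.fill_diagonal(sub, np.inf)
    assert sub.min(initial=np.inf) >= min_dist_km, "thinning violated the distance constraint"

    records = occ.records[best].reset_index(drop=True)
    log = dict(occ.log)
    log["n_thinned_out"] = int(n - best.sum())
    return OccurrenceSet(occ.species_id, records, occ.group, float(min_dist_km), log)
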