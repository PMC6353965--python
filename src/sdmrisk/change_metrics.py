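"""Biodiversity-change surfaces and IUCN A3(c) threat classification.

Species richness is the cell-wise sum of per-species suitability (the
expected species count when suitabilities are read as relative
likelihoods); temporal turnover is the per-cell Bray-Curtis dissimilarity
between current and future species composition. Range change is computed
on binarized ranges under two dispersal scenarios — Unlimited Dispersal
(UD: the projected future range as is) and No Dispersal (ND: the future
range intersected with the current range) — and mapped onto IUCN Red List
criterion A3(c) categories: Extinct at 100% projected range loss,
Critically Endangered above 80%, Endangered above 50%, Vulnerable above
30% (strict inequalities; equals fall in the less severe class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "SEVERITY",
    "ThreatRecord",
    "richness",
    "temporal_turnover",
    "apply_dispersal",
    "range_change_pct",
    "classify_threat",
    "make_threat_record",
    "summarize_assessment",
]

CATEGORIES = ("LC", "VU", "EN", "CR", "EX", "Expanding")

#: Severity rank used for the ND >= UD monotonicity property; an expanding
#: range is no more severe than Least Concern.
SEVERITY = {"Expanding": 0, "LC": 0, "VU": 1, "EN": 2, "CR": 3, "EX": 4}


def _stack_surfaces(surfaces: dict[str, np.ndarray]) -> np.ndarray:
    shapes = {np.asarray(s).shape for s in surfaces.values()}
    if len(shapes) != 1:
        raise ValueError(f"species surfaces on different grids: {shapes}")
    return np.stack([np.asarray(surfaces[k], dtype=float) for k in sorted(surfaces)])


def richness(surfaces: dict[str, np.ndarray]) -> np.ndarray:
    """Expected species count per cell: sum of suitabilities over species.

    Masked (NaN) cells propagate. Accepts continuous suitabilities or
    binary ranges (then the result is an integer species count).
    """
    if not surfaces:
        raise ValueError("need at least one species surface")
    return _stack_surfaces(surfaces).sum(axis=0)


def temporal_turnover(
    current: dict[str, np.ndarray], future: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell Bray-Curtis dissimilarity between current and future composition.

    BC = sum_s |c_s - f_s| / sum_s (c_s + f_s); 0 means no change in
    composition, 1 a complete change. Cells empty in both periods have no
    defined composition; they are reported as 0 and flagged in the second
    returned array.
    """
    if set(current) != set(future):
        raise ValueError(
            f"species sets differ: {sorted(set(current) ^ set(future))} not shared"
        )
    c = _stack_surfaces(current)
    f = _stack_surfaces(future)
    if c.shape != f.shape:
        raise ValueError("current and future stacks on different grids")
    num = np.abs(c - f).sum(axis=0)
    den = (c + f).sum(axis=0)
    both_empty = den == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(both_empty, 0.0, num / den)
    bc[np.isnan(den)] = np.nan
    return bc, both_empty & ~np.isnan(den)


def apply_dispersal(
    current_range: np.ndarray, future_range: np.ndarray, scenario: str
) -> np.ndarray:
    """Effective future range under a dispersal scenario.

    UD (unlimited dispersal) keeps the projected future range; ND (no
    dispersal) removes projected habitat the species cannot reach, i.e.
    intersects the future range with the current one.
    """
    current_range = np.asarray(current_range, dtype=bool)
    future_range = np.asarray(future_range, dtype=bool)
    if current_range.shape != future_range.shape:
        raise ValueError("range rasters on different grids")
    if scenario == "UD":
        return future_range.copy()
    if scenario == "ND":
        return future_range & current_range
    raise ValueError(f"unknown dispersal scenario {scenario!r}; use 'UD' or 'ND'")


def range_change_pct(current_cells: int, future_cells: int) -> float:
    """Percent range change, negative for loss: 100 x (future - current) / current."""
    if current_cells <= 0:
        raise ValueError("current range is empty; change undefined")
    return 100.0 * (future_cells - current_cells) / current_cells


def classify_threat(change_pct: float) -> str:
    """IUCN A3(c) category from percent range change (negative = loss).

    Thresholds are strict: a loss of exactly 80% is EN, exactly 50% is VU,
    exactly 30% is LC. A positive change is classed as Expanding.
    """
    if not np.isfinite(change_pct) or change_pct < -100.0:
        raise ValueError(f"invalid range change {change_pct}%: must be in [-100, inf)")
    if change_pct > 0:
        return "Expanding"
    loss = -change_pct
    if loss == 100.0:
        return "EX"
    if loss > 80.0:
        return "CR"
    if loss > 50.0:
        return "EN"
    if loss > 30.0:
        return "VU"
    return "LC"


@dataclass(frozen=True)
class ThreatRecord:
    """Per species x horizon x dispersal scenario assessment outcome."""

    species_id: str
    horizon: str
    scenario: str
    current_cells: int
    future_cells: int
    change_pct: float
    category: str


def make_threat_record(
    species_id: str,
    horizon: str,
    scenario: str,
    current_range: np.ndarray,
    future_range: np.ndarray,
) -> ThreatRecord:
    """Apply the dispersal scenario, compute range change, classify."""
    effective = apply_dispersal(current_range, future_range, scenario)
    cur = int(np.asarray(current_range, dtype=bool).sum())
    fut = int(effective.sum())
    change = range_change_pct(cur, fut)
    return ThreatRecord(species_id, horizon, scenario, cur, fut, change, classify_threat(change))


LOSS_BANDS = (
    (">30%", 30.0, 100.0),
    ("50-100%", 50.0, 100.0),
    ("100%", 100.0, 100.0),
)


def summarize_assessment(
    records: list[ThreatRecord],
    current_categories: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Cohort tables from per-species threat records.

    Returns ``band_counts`` (species counts per loss band per horizon x
    scenario; bands overlap by construction: ">30%" contains "50-100%"
    contains "100%"), ``category_counts`` and a current-vs-predicted
    category ``transitions`` matrix (current categories default to LC).
    """
    frame = pd.DataFrame([r.__dict__ for r in records])
    if frame.empty:
        empty = pd.DataFrame()
        return {"records": frame, "band_counts": empty, "category_counts": empty, "transitions": empty}
    keys = frame[["species_id", "horizon", "scenario"]]
    if keys.duplicated().any():
        dupes = keys[keys.duplicated()].to_dict("records")
        raise ValueError(f"duplicate species-horizon-scenario records: {dupes}")

    frame["loss_pct"] = -frame["change_pct"]
    rows = []
    for (horizon, scenario), g in frame.groupby(["horizon", "scenario"]):
        row = {"horizon": horizon, "scenario": scenario, "n_species": len(g)}
        for label, lo, hi in LOSS_BANDS:
            if lo == hi:
                row[label] = int((g["loss_pct"] == lo).sum())
            else:
                row[label] = int(((g["loss_pct"] > lo) & (g["loss_pct"] <= hi)).sum())
        rows.append(row)
    band_counts = pd.DataFrame(rows)

    category_counts = (
        frame.groupby(["horizon", "scenario", "category"]).size().rename("n").reset_index()
    )

    cur = current_categories or {}
    frame["current_category"] = [cur.get(s, "LC") for s in frame["species_id"]]
    transitions = pd.crosstab(frame["current_category"], frame["category"])

    return {
        "records": frame.drop(columns=["loss_pct"]),
        "band_counts": band_counts,
        "category_counts": category_counts,
        "transitions": transitions,
    }
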