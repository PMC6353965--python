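"""Run configuration and full-pipeline orchestration.

``run_pipeline`` drives the whole assessment for every species in an
occurrence file: cleaning and dispersal-group thinning, VIF predictor
pruning, calibration-region construction, ensemble fitting with
spatial-block CV, clamped projection onto per-GCM future stacks with
cell-median aggregation, binarization, dispersal scenarios, A3(c)
classification, and community richness/turnover surfaces. Each species
is an independent work unit; a failure is recorded in the manifest and
the run continues. All randomness derives from one root seed, split
deterministically per species, so reruns with an identical configuration
are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import change_metrics as cm
from . import io as sio
from .calibration import build_calibration_region
from .ensemble import EnsembleSDM, build_training_data, consensus_predict, project_future
from .grids import set_train_bounds
from .occurrences import GROUP_THIN_KM, clean_records, spatial_thin
from .predictors import build_future_stacks, clamp, vif_stepwise

logger = logging.getLogger("sdmrisk")

__all__ = ["RunConfig", "species_seed", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs; serialized into the output dir."""

    occurrences: str
    current_stack: str
    future_stacks: dict[str, list[str]] = field(default_factory=dict)  # horizon -> GCM dirs
    species_groups: dict[str, str] = field(default_factory=dict)
    default_group: str = "small"
    thin_km: dict[str, float] = field(default_factory=lambda: dict(GROUP_THIN_KM))
    thin_tries: int = 100
    year_min: int = 1960
    year_max: int = 2005
    vif_threshold: float = 10.0
    vif_sample_cells: int = 10_000
    n_background: int = 10_000
    min_contribution: float = 5.0
    algorithms: str | list[str] = "auto"
    n_permutations: int = 5
    scenarios: tuple[str, ...] = ("UD", "ND")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        obj = asdict(self)
        obj["scenarios"] = list(self.scenarios)
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def species_seed(root_seed: int, species_id: str) -> int:
    """Deterministic per-species seed independent of processing order."""
    digest = hashlib.sha256(f"{root_seed}:{species_id}".encode()).hexdigest()
    return int(digest[:8], 16) % 2**31


def _run_one_species(
    sid: str, records: pd.DataFrame, stack, future_by_horizon, config: RunConfig, outdir: Path
) -> tuple[list[cm.ThreatRecord], dict, dict[str, np.ndarray]]:
    """Full per-species workflow; returns threat records, metadata, surfaces."""
    seed = species_seed(config.seed, sid)
    group = config.species_groups.get(sid, config.default_group)
    occ = clean_records(
        records, stack.grid, config.year_min, config.year_max, species_id=sid, group=group
    )
    occ = spatial_thin(occ, config.thin_km[group], n_tries=config.thin_tries, seed=seed)
    if len(occ) < 5:
        raise ValueError(f"only {len(occ)} records after cleaning/thinning (minimum 5)")

    region = build_calibration_region(occ, stack, n_background=config.n_background, seed=seed)
    prow, pcol = stack.grid.cell_of(occ.lons, occ.lats)
    train_cells = np.union1d(region.cells, prow * stack.grid.n_cols + pcol)
    stack_b = set_train_bounds(stack, train_cells)

    X, y, blocks, _ = build_training_data(occ, region, stack_b)
    model = EnsembleSDM(
        algorithms=config.algorithms,
        min_contribution=config.min_contribution,
        n_permutations=config.n_permutations,
        random_state=seed,
    ).fit(X, y, blocks=blocks, feature_names=stack_b.layer_names)

    current = consensus_predict(model, clamp(stack_b), sid, "current")
    cur_range = current.binary_range()

    spdir = outdir / "species" / sid
    spdir.mkdir(parents=True, exist_ok=True)
    sio.write_ascii_grid(spdir / "suitability_current.asc", stack.grid, current.values)
    sio.write_geojson(
        spdir / "calibration_region.geojson",
        region.polygon,
        {
            "species": sid,
            "buffer_km": region.buffer_km,
            "used_full_area": region.used_full_area,
            "area_fraction": region.area_fraction,
        },
    )

    surfaces = {"current": current.values}
    threat_records: list[cm.ThreatRecord] = []
    for horizon, gcm_stacks in future_by_horizon.items():
        futures = [clamp(s) for s in build_future_stacks(stack_b, gcm_stacks)]
        proj = project_future(model, futures, sid, horizon)
        surfaces[horizon] = proj.values
        sio.write_ascii_grid(spdir / f"suitability_{horizon}.asc", stack.grid, proj.values)
        fut_range = proj.binary_range()
        for scenario in config.scenarios:
            threat_records.append(
                cm.make_threat_record(sid, horizon, scenario, cur_range, fut_range)
            )

    meta = {
        "group": group,
        "seed": seed,
        "cleaning_log": occ.log,
        "n_records": len(occ),
        "buffer_km": region.buffer_km,
        "used_full_area": region.used_full_area,
        "retained_predictors": model.retained_predictors_,
        "cv_auc": model.cv_auc_,
        "cv_tss": model.cv_tss_,
        "threshold": model.threshold_,
        "member_cv": model.member_cv_.to_dict("records"),
    }
    return threat_records, meta, surfaces


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full assessment; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    occ_all, n_bad = sio.read_occurrences(config.occurrences)
    stack = sio.read_stack(config.current_stack)

    # collinearity pruning on the current predictors; future survivor sets
    # are recorded and current/future disagreements flagged, but the
    # current-data survivors are what the models use
    retained, vif_table = vif_stepwise(
        stack, config.vif_sample_cells, config.vif_threshold, seed=config.seed
    )
    vif_table.to_csv(outdir / "vif_current.csv", index=False)

    # future predictor sets get their own VIF pass; disagreements with the
    # current-data survivor set are only flagged — the current survivors are
    # what the models use
    future_by_horizon: dict[str, list] = {}
    future_violations: dict[str, list[str]] = {}
    for horizon, dirs in config.future_stacks.items():
        gcms = [sio.read_stack(d) for d in dirs]
        future_by_horizon[horizon] = gcms
        fut_names = [n for n in retained if n in gcms[0].layers]
        if len(fut_names) >= 2:
            fut_retained, fut_table = vif_stepwise(
                gcms[0].subset(fut_names),
                config.vif_sample_cells,
                config.vif_threshold,
                seed=config.seed,
            )
            fut_table.to_csv(outdir / f"vif_{horizon}.csv", index=False)
            dropped = sorted(set(fut_names) - set(fut_retained))
            if dropped:
                future_violations[horizon] = dropped
                logger.warning(
                    "horizon %s: layers %s violate the VIF threshold in the future "
                    "predictor set; current-data survivors retained", horizon, dropped,
                )
    stack = stack.subset(retained)

    manifest: dict = {
        "seed": config.seed,
        "n_malformed_occurrence_rows": n_bad,
        "retained_predictors": retained,
        "future_vif_violations": future_violations,
        "species": {},
        "artifacts": {},
    }

    all_records: list[cm.ThreatRecord] = []
    current_surfaces: dict[str, np.ndarray] = {}
    future_surfaces: dict[str, dict[str, np.ndarray]] = {
        h: {} for h in future_by_horizon
    }
    for sid, records in occ_all.groupby("species", sort=True):
        try:
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message=".*background cells available.*")
                recs, meta, surfaces = _run_one_species(
                    sid, records, stack, future_by_horizon, config, outdir
                )
        except Exception as exc:  # noqa: BLE001 — isolate per-species failures
            logger.warning("species %s failed: %s", sid, exc)
            manifest["species"][sid] = {"status": "failed", "reason": str(exc)}
            continue
        manifest["species"][sid] = {"status": "ok", **meta}
        all_records.extend(recs)
        current_surfaces[sid] = surfaces["current"]
        for h in future_by_horizon:
            future_surfaces[h][sid] = surfaces[h]

    # community surfaces and cohort tables
    if current_surfaces:
        rich = cm.richness(current_surfaces)
        sio.write_ascii_grid(outdir / "richness_current.asc", stack.grid, rich)
        for h, surfs in future_surfaces.items():
            if surfs:
                sio.write_ascii_grid(outdir / f"richness_{h}.asc", stack.grid, cm.richness(surfs))
                bc, _ = cm.temporal_turnover(current_surfaces, surfs)
                sio.write_ascii_grid(outdir / f"turnover_{h}.asc", stack.grid, bc)
    tables = cm.summarize_assessment(all_records)
    tables["records"].to_csv(outdir / "threat_records.csv", index=False)
    tables["band_counts"].to_csv(outdir / "loss_band_counts.csv", index=False)
    tables["category_counts"].to_csv(outdir / "category_counts.csv", index=False)

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["artifacts"][str(path.relative_to(outdir))] = sio.file_sha256(path)
    sio.write_manifest(outdir / "manifest.json", manifest)
    return manifest
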