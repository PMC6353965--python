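"""End-to-end virtual-species truth-recovery experiments.

A self-contained benchmark of the whole pipeline against known ground
truth: a spatially autocorrelated virtual landscape, species with
parametric Gaussian niches on a subset of predictors, presence-only
sampling, cleaning/thinning, calibration-region construction, ensemble
fitting with spatial-block CV, clamped projection onto pseudo-GCM future
stacks (cell-median across GCMs), binarization, and A3(c) classification
under both dispersal scenarios — compared per species against the
engineered true range change.

Used both by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import change_metrics as cm
from .calibration import build_calibration_region
from .ensemble import EnsembleSDM, build_training_data, consensus_predict, project_future
from .grids import ARC_MIN_2_5, EnvStack, GridSpec, set_train_bounds
from .occurrences import clean_records, spatial_thin
from .predictors import build_future_stacks, clamp
from .synthetic import (
    SamplingDesign,
    add_future_truth,
    generate_env_stack,
    make_future_stack,
    make_virtual_species,
    sample_occurrences,
    shift_stack,
)

__all__ = ["ExperimentDesign", "run_virtual_experiment"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Study conditions for one virtual experiment.

    Defaults: a 100x100 cell landscape at 2.5 arc-min with 6 independent
    predictors of which the first 3 carry the species' niches, 100
    presences per species, 5 km thinning (small-mammal default), 4
    pseudo-GCMs, and additive climate shifts of +0.8 sd by 2050 and
    +1.3 sd by 2070 on all dynamic layers.

    Species are narrow-niched habitat specialists (sigma 0.25-0.5 sd of
    the landscape layers), matching the narrow-ranged endemics the method
    targets. The truth range is "potential range": all cells with
    suitability at or above a small occupancy floor (0.05). That floor is
    deliberately commensurable with the max-TSS operational threshold of
    a presence-background model, which sits near the mean landscape
    suitability rather than near the niche core — a core-habitat cutoff
    (e.g. 0.5) would make truth and estimate measure different things no
    matter how good the model is (see the methods note).
    """

    n_species: int = 20
    grid_size: int = 100
    n_layers: int = 6
    n_informative: int = 3
    autocorr_range: float = 10.0
    n_presences: int = 100
    duplicate_rate: float = 0.05
    thin_km: float = 5.0
    thin_tries: int = 30
    n_background: int = 10_000
    n_gcms: int = 4
    gcm_noise_sd: float = 0.15
    horizon_shifts: tuple[tuple[str, float], ...] = (("2050", 0.8), ("2070", 1.3))
    mu_range: tuple[float, float] = (-1.0, 1.0)
    sigma_range: tuple[float, float] = (0.25, 0.5)
    range_cutoff: float = 0.05
    min_range_cells: int = 100
    max_range_fraction: float = 0.3


def _draw_species_truth(env: EnvStack, design: ExperimentDesign, rng: np.random.Generator):
    """Draw niche parameters until the implied current range is usable."""
    names = env.layer_names[: design.n_informative]
    n_cells = env.grid.n_cells
    for _ in range(200):
        params = {
            n: (rng.uniform(*design.mu_range), rng.uniform(*design.sigma_range))
            for n in names
        }
        truth = make_virtual_species(env, params, range_cutoff=design.range_cutoff)
        n_range = int(truth.true_current_range.sum())
        if design.min_range_cells <= n_range <= design.max_range_fraction * n_cells:
            return truth
    raise RuntimeError("could not draw a species with a usable range in 200 tries")


def run_virtual_experiment(
    design: ExperimentDesign = ExperimentDesign(), seed: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Run the full pipeline over ``design.n_species`` virtual species.

    Returns a tidy frame with one row per species x horizon (CV scores,
    estimated and true range change, categories under UD and ND, current
    range overlap) and an ``extras`` dict with community-level summaries
    (richness decline and mean turnover per horizon).
    """
    root = np.random.SeedSequence(seed)
    landscape_seed, *species_seeds = root.spawn(design.n_species + 1)

    grid = GridSpec(
        n_rows=design.grid_size, n_cols=design.grid_size,
        cell_size=ARC_MIN_2_5, origin_lon=10.0, origin_lat=30.0,
    )
    env = generate_env_stack(
        grid, design.n_layers, autocorr_range=design.autocorr_range,
        seed=int(landscape_seed.generate_state(1)[0] % 2**31),
    )
    shifts = {
        h: {n: ("add", d) for n in env.dynamic_names} for h, d in design.horizon_shifts
    }
    true_future_env = {h: shift_stack(env, s) for h, s in shifts.items()}

    rows = []
    current_surfaces: dict[str, np.ndarray] = {}
    future_surfaces: dict[str, dict[str, np.ndarray]] = {h: {} for h, _ in design.horizon_shifts}

    for i, seq in enumerate(species_seeds):
        sid = f"sp_{i:02d}"
        rng = np.random.default_rng(seq)
        sp_seed = int(seq.generate_state(1)[0] % 2**31)

        truth = _draw_species_truth(env, design, rng)
        for h, _ in design.horizon_shifts:
            add_future_truth(truth, true_future_env[h], h)

        samp = SamplingDesign(
            n_presences=design.n_presences,
            duplicate_rate=design.duplicate_rate,
            seed=sp_seed,
        )
        raw = sample_occurrences(truth, grid, samp, species_id=sid)
        occ = clean_records(raw, grid, species_id=sid, group="small")
        occ = spatial_thin(occ, design.thin_km, n_tries=design.thin_tries, seed=sp_seed)

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*background cells available.*")
            warnings.filterwarnings("ignore", message=".*records: 4-block.*")
            region = build_calibration_region(
                occ, env, n_background=design.n_background, seed=sp_seed
            )
            prow, pcol = grid.cell_of(occ.lons, occ.lats)
            train_cells = np.union1d(region.cells, prow * grid.n_cols + pcol)
            env_b = set_train_bounds(env, train_cells)

            X, y, blocks, _ = build_training_data(occ, region, env_b)
            model = EnsembleSDM(random_state=sp_seed).fit(
                X, y, blocks=blocks, feature_names=env_b.layer_names
            )

            current = consensus_predict(model, clamp(env_b), sid, "current")
            cur_range = current.binary_range()
            current_surfaces[sid] = current.values

            gcm_seed = int(seq.generate_state(2)[1] % 2**31)
            for h, _delta in design.horizon_shifts:
                gcms = make_future_stack(
                    env, shifts[h], design.n_gcms, design.gcm_noise_sd, seed=gcm_seed
                )
                futures = [clamp(s) for s in build_future_stacks(env_b, gcms)]
                proj = project_future(model, futures, sid, h)
                future_surfaces[h][sid] = proj.values
                fut_range = proj.binary_range()

                rec_ud = cm.make_threat_record(sid, h, "UD", cur_range, fut_range)
                rec_nd = cm.make_threat_record(sid, h, "ND", cur_range, fut_range)
                true_change = truth.true_range_change_pct[h]
                inter = (cur_range & truth.true_current_range).sum()
                union = (cur_range | truth.true_current_range).sum()
                rows.append(
                    {
                        "species": sid,
                        "horizon": h,
                        "n_thinned": len(occ),
                        "cv_auc": model.cv_auc_,
                        "cv_tss": model.cv_tss_,
                        "threshold": model.threshold_,
                        "jaccard_current": inter / union if union else np.nan,
                        "est_change_ud": rec_ud.change_pct,
                        "est_change_nd": rec_nd.change_pct,
                        "true_change": true_change,
                        "est_category_ud": rec_ud.category,
                        "est_category_nd": rec_nd.category,
                        "true_category": cm.classify_threat(true_change),
                    }
                )

    frame = pd.DataFrame(rows)
    extras: dict = {"design": design}
    rich_cur = cm.richness(current_surfaces)
    total_cur = np.nansum(rich_cur)
    for h, _ in design.horizon_shifts:
        rich_fut = cm.richness(future_surfaces[h])
        extras[f"richness_decline_pct_{h}"] = float(
            100.0 * (1.0 - np.nansum(rich_fut) / total_cur)
        )
        bc, _flag = cm.temporal_turnover(current_surfaces, future_surfaces[h])
        extras[f"mean_turnover_{h}"] = float(np.nanmean(bc))
    return frame, extras
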