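"""Virtual landscapes and virtual species with known ground truth.

Every downstream stage of the pipeline can be exercised against simulated
inputs whose generating process is fully known: spatially autocorrelated,
cross-correlated environmental layers; species whose suitability is an
explicit parametric function of a few layers; presence records sampled
proportionally to suitability (optionally spatially biased and with
duplicated records); and future layer stacks derived from the current ones
by known shifts plus per-"GCM" perturbations.

All operations are pure functions of their inputs and a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import EnvStack, GridSpec

__all__ = [
    "SamplingDesign",
    "VirtualSpeciesTruth",
    "generate_env_stack",
    "make_virtual_species",
    "evaluate_suitability",
    "add_future_truth",
    "sample_occurrences",
    "shift_stack",
    "make_future_stack",
]


# ---------------------------------------------------------------------------
# random fields
# ---------------------------------------------------------------------------

def _exponential_field_spectrum(shape: tuple[int, int], autocorr_range: float) -> np.ndarray:
    """Eigenvalues of the circulant embedding of an exponential correlogram.

    The target stationary covariance is C(d) = exp(-d / range) with d the
    torus (wrap-around) cell distance; its 2-D FFT gives the spectrum of the
    circulant covariance operator. Tiny negative eigenvalues from imperfect
    embedding are clipped to zero.
    """
    n_rows, n_cols = shape
    ry = np.minimum(np.arange(n_rows), n_rows - np.arange(n_rows))
    rx = np.minimum(np.arange(n_cols), n_cols - np.arange(n_cols))
    d = np.hypot(ry[:, None], rx[None, :])
    cov = np.exp(-d / float(autocorr_range))
    lam = np.fft.fft2(cov).real
    return np.clip(lam, 0.0, None)


def generate_env_stack(
    grid: GridSpec,
    n_layers: int,
    autocorr_range: float = 10.0,
    cross_corr: np.ndarray | None = None,
    seed: int = 0,
    names: list[str] | None = None,
) -> EnvStack:
    """Generate ``n_layers`` co-registered Gaussian random field layers.

    Each layer is a stationary random field with an exponential correlogram
    of the requested range (in cells), standardized to mean 0 / sd 1.
    Cross-layer correlation is imposed by Cholesky mixing of independent
    fields, so empirical inter-layer correlations converge to ``cross_corr``
    as the grid grows.

    Parameters
    ----------
    cross_corr : array, optional
        Symmetric positive semi-definite matrix with unit diagonal,
        dimension ``n_layers``. Identity (independent layers) by default.
    """
    if cross_corr is None:
        cross_corr = np.eye(n_layers)
    cross_corr = np.asarray(cross_corr, dtype=float)
    if cross_corr.shape != (n_layers, n_layers):
        raise ValueError(f"cross_corr must be {n_layers}x{n_layers}, got {cross_corr.shape}")
    if not np.allclose(cross_corr, cross_corr.T):
        raise ValueError("cross_corr must be symmetric")
    if not np.allclose(np.diag(cross_corr), 1.0):
        raise ValueError("cross_corr must have unit diagonal")
    eigvals = np.linalg.eigvalsh(cross_corr)
    if eigvals[0] < -1e-10:
        raise ValueError(
            f"cross_corr is not positive semi-definite: smallest eigenvalue {eigvals[0]:.6g}"
        )

    rng = np.random.default_rng(seed)
    lam = _exponential_field_spectrum(grid.shape, autocorr_range)
    fields = np.empty((n_layers, grid.n_rows, grid.n_cols))
    for k in range(n_layers):
        noise = rng.standard_normal(grid.shape)
        f = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(noise)).real
        fields[k] = (f - f.mean()) / f.std()

    # eigen square root handles singular (perfectly correlated) targets
    w, v = np.linalg.eigh(cross_corr)
    mix = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    mixed = np.tensordot(mix, fields, axes=(1, 0))
    mixed = (mixed - mixed.mean(axis=(1, 2), keepdims=True)) / mixed.std(
        axis=(1, 2), keepdims=True
    )

    if names is None:
        names = [f"env_{k + 1:02d}" for k in range(n_layers)]
    if len(names) != n_layers:
        raise ValueError("names length must equal n_layers")
    return EnvStack(grid=grid, layers={n: mixed[k] for k, n in enumerate(names)})


# ---------------------------------------------------------------------------
# virtual species
# ---------------------------------------------------------------------------

@dataclass
class VirtualSpeciesTruth:
    """Known generating truth for one virtual species.

    ``niche_params`` maps each active predictor to its optimum ``mu`` and
    breadth ``sigma`` (predictor units). Suitability lies in [0, 1]; the
    true range is ``suitability >= range_cutoff``. Future truth surfaces
    and the implied true range change are attached per horizon by
    :func:`add_future_truth`.
    """

    niche_params: dict[str, tuple[float, float]]
    suitability_fn_kind: str
    range_cutoff: float
    suitability: np.ndarray
    true_current_range: np.ndarray
    true_future_range: dict[str, np.ndarray] = field(default_factory=dict)
    true_range_change_pct: dict[str, float] = field(default_factory=dict)

    @property
    def active_predictors(self) -> list[str]:
        return list(self.niche_params)

    def to_json(self, path) -> None:
        obj = {
            "niche_params": {k: list(v) for k, v in self.niche_params.items()},
            "suitability_fn_kind": self.suitability_fn_kind,
            "range_cutoff": self.range_cutoff,
            "true_current_cells": int(self.true_current_range.sum()),
            "true_future_cells": {k: int(v.sum()) for k, v in self.true_future_range.items()},
            "true_range_change_pct": self.true_range_change_pct,
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def _suitability_from_matrix(
    X: np.ndarray, mus: np.ndarray, sigmas: np.ndarray, kind: str
) -> np.ndarray:
    if kind == "gaussian-product":
        z2 = ((X - mus) / sigmas) ** 2
        return np.exp(-0.5 * z2.sum(axis=1))
    if kind == "logistic-additive":
        z = ((X - mus) / sigmas).sum(axis=1)
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown suitability_fn_kind {kind!r}")


def evaluate_suitability(
    env: EnvStack,
    niche_params: dict[str, tuple[float, float]],
    kind: str = "gaussian-product",
) -> np.ndarray:
    """Cell-wise suitability surface in [0, 1]; NaN on masked cells."""
    missing = [n for n in niche_params if n not in env.layers]
    if missing:
        raise KeyError(f"active predictors absent from stack: {missing}")
    names = list(niche_params)
    mus = np.array([niche_params[n][0] for n in names])
    sigmas = np.array([niche_params[n][1] for n in names])
    if np.any(sigmas <= 0):
        raise ValueError("niche breadths sigma must be positive")
    surf = np.full(env.grid.shape, np.nan)
    cells = env.valid_cells()
    X = env.to_matrix(names, cells)
    surf.ravel()[cells] = _suitability_from_matrix(X, mus, sigmas, kind)
    return surf


def make_virtual_species(
    env: EnvStack,
    niche_params: dict[str, tuple[float, float]],
    suitability_fn_kind: str = "gaussian-product",
    range_cutoff: float = 0.5,
) -> VirtualSpeciesTruth:
    """Build a virtual species truth object from a parametric niche."""
    suit = evaluate_suitability(env, niche_params, suitability_fn_kind)
    return VirtualSpeciesTruth(
        niche_params=dict(niche_params),
        suitability_fn_kind=suitability_fn_kind,
        range_cutoff=float(range_cutoff),
        suitability=suit,
        true_current_range=suit >= range_cutoff,
    )


def add_future_truth(
    truth: VirtualSpeciesTruth, future_env: EnvStack, horizon: str
) -> VirtualSpeciesTruth:
    """Attach the true future range and range change for one horizon.

    The change percentage is computed by the same definition used for model
    output (:func:`sdmrisk.change_metrics.range_change_pct`), so truth and
    estimate are directly comparable.
    """
    from .change_metrics import range_change_pct

    suit = evaluate_suitability(future_env, truth.niche_params, truth.suitability_fn_kind)
    fut_range = suit >= truth.range_cutoff
    truth.true_future_range[horizon] = fut_range
    truth.true_range_change_pct[horizon] = range_change_pct(
        int(truth.true_current_range.sum()), int(fut_range.sum())
    )
    return truth


# ---------------------------------------------------------------------------
# occurrence sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingDesign:
    """How presences are drawn from a suitability surface.

    ``bias_surface``, if given, is a nonnegative relative sampling-intensity
    raster on the same grid (multiplies suitability). ``duplicate_rate`` is
    the probability that a drawn record is emitted twice verbatim,
    emulating multi-source compilations.
    """

    n_presences: int = 100
    bias_surface: np.ndarray | None = None
    duplicate_rate: float = 0.0
    year_range: tuple[int, int] = (1960, 2005)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_presences < 1:
            raise ValueError("n_presences must be >= 1")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must be a probability")


def sample_occurrences(
    truth: VirtualSpeciesTruth,
    grid: GridSpec,
    design: SamplingDesign,
    species_id: str = "virtual",
) -> pd.DataFrame:
    """Draw presence records with probability proportional to suitability.

    Cells are drawn (with replacement) with weight suitability x bias;
    coordinates are jittered uniformly within the source cell. Returns a
    frame with columns species, lon, lat, year, source.
    """
    weight = np.nan_to_num(truth.suitability, nan=0.0).ravel().copy()
    if design.bias_surface is not None:
        bias = np.asarray(design.bias_surface, dtype=float)
        if bias.shape != grid.shape:
            raise ValueError("bias_surface must be on the shared grid")
        if np.any(bias < 0):
            raise ValueError("bias_surface must be nonnegative")
        weight *= np.nan_to_num(bias, nan=0.0).ravel()
    total = weight.sum()
    if total <= 0:
        raise ValueError("total sampling weight is zero: suitability x bias has no support")

    rng = np.random.default_rng(design.seed)
    cells = rng.choice(weight.size, size=design.n_presences, p=weight / total)
    rows, cols = np.divmod(cells, grid.n_cols)
    jitter_lon = rng.uniform(0.0, 1.0, design.n_presences)
    jitter_lat = rng.uniform(0.0, 1.0, design.n_presences)
    lons = grid.origin_lon + (cols + jitter_lon) * grid.cell_size
    lats = grid.origin_lat - (rows + jitter_lat) * grid.cell_size
    years = rng.integers(design.year_range[0], design.year_range[1] + 1, design.n_presences)

    frame = pd.DataFrame(
        {
            "species": species_id,
            "lon": lons,
            "lat": lats,
            "year": years,
            "source": "virtual",
        }
    )
    if design.duplicate_rate > 0:
        dup = rng.random(design.n_presences) < design.duplicate_rate
        frame = pd.concat([frame, frame[dup]], ignore_index=True)
    return frame


# ---------------------------------------------------------------------------
# pseudo-futures and pseudo-GCMs
# ---------------------------------------------------------------------------

def shift_stack(env: EnvStack, shift: dict[str, tuple[str, float]]) -> EnvStack:
    """Apply known additive/multiplicative per-layer shifts to dynamic layers.

    ``shift`` maps layer name to ``("add", delta)`` or ``("mul", factor)``.
    Layers flagged static must not be shifted.
    """
    out = env.copy()
    for name, (mode, value) in shift.items():
        if name not in out.layers:
            raise KeyError(f"shift names nonexistent layer {name!r}")
        if out.static_flags[name]:
            raise ValueError(f"layer {name!r} is static and must not be shifted")
        if mode == "add":
            out.layers[name] = out.layers[name] + value
        elif mode == "mul":
            out.layers[name] = out.layers[name] * value
        else:
            raise ValueError(f"unknown shift mode {mode!r}")
    return out


def make_future_stack(
    env: EnvStack,
    shift: dict[str, tuple[str, float]],
    n_gcms: int = 4,
    gcm_noise_sd: float = 0.0,
    seed: int = 0,
) -> list[EnvStack]:
    """Build ``n_gcms`` pseudo-GCM future stacks.

    Each stack is the shifted current stack plus independent zero-mean
    Gaussian perturbations of sd ``gcm_noise_sd`` on dynamic layers; static
    layers are copied bit-identical from the current stack.
    """
    base = shift_stack(env, shift)
    rng = np.random.default_rng(seed)
    stacks = []
    for _ in range(n_gcms):
        gcm = base.copy()
        for name in gcm.dynamic_names:
            if gcm_noise_sd > 0:
                gcm.layers[name] = gcm.layers[name] + rng.normal(
                    0.0, gcm_noise_sd, env.grid.shape
                )
        stacks.append(gcm)
    return stacks
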