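"""Predictor screening and projection safety: VIF pruning, ExDet, clamping.

Collinear predictor sets inflate model variance and make projections
unstable; predictors are pruned by iteratively removing the layer with
the largest variance inflation factor VIF_j = 1 / (1 - R^2_j) until all
remaining VIFs are at or below a threshold (default 10). Projections
onto future conditions are protected by clamping predictor values into
their training ranges and by ExDet novelty surfaces flagging univariate
(NT1) and combinatorial (NT2) non-analogue environments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .grids import EnvStack, check_same_grid

__all__ = [
    "VIFSelector",
    "vif_stepwise",
    "build_future_stacks",
    "ExDetSurface",
    "exdet",
    "exdet_arrays",
    "clamp",
]

_VIF_INF_R2 = 1.0 - 1e-12


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF of each column of X regressed on the remaining columns.

    Plain least squares with an intercept; R^2 numerically at 1 (perfect
    collinearity) yields an infinite VIF.
    """
    n, p = X.shape
    vifs = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            vifs[j] = np.inf  # constant column: undefined, treat as worst
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        vifs[j] = np.inf if r2 >= _VIF_INF_R2 else 1.0 / (1.0 - r2)
    return vifs


class VIFSelector(SelectorMixin, BaseEstimator):
    """Stepwise collinearity filter on variance inflation factors.

    While any feature has VIF above ``threshold``, the single feature with
    the largest VIF is removed (exact ties broken by removing the
    alphabetically first name) and all VIFs are recomputed. Survivors all
    have VIF <= threshold.

    Attributes
    ----------
    support_ : bool array of shape (n_features,)
        Mask of retained features.
    retained_ : list of str
        Names of retained features.
    vif_table_ : DataFrame
        Per-round VIF values with the removed feature flagged, one row per
        (round, feature).
    """

    def __init__(self, threshold: float = 10.0):
        self.threshold = threshold

    def fit(self, X, y=None, feature_names: list[str] | None = None):
        X = validate_data(self, X, ensure_min_features=2)
        n, p = X.shape
        if feature_names is None:
            feature_names = getattr(self, "feature_names_in_", None)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]
        names = list(feature_names)

        active = list(range(p))
        rows = []
        round_no = 0
        while len(active) >= 2:
            round_no += 1
            vifs = _vif_values(X[:, active])
            worst = np.nanmax(vifs)
            remove_local: int | None = None
            if worst > self.threshold:
                ties = np.flatnonzero(
                    np.isclose(vifs, worst, rtol=1e-9, atol=0.0) | (np.isinf(vifs) & np.isinf(worst))
                )
                # deterministic tie-break: alphabetically first name
                remove_local = min(ties, key=lambda k: names[active[k]])
            for k, idx in enumerate(active):
                rows.append(
                    {
                        "round": round_no,
                        "feature": names[idx],
                        "vif": vifs[k],
                        "removed": remove_local == k,
                    }
                )
            if remove_local is None:
                break
            del active[remove_local]

        self.retained_ = [names[i] for i in active]
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[active] = True
        self.vif_table_ = pd.DataFrame(rows)
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


def vif_stepwise(
    stack: EnvStack,
    sample_cells: int = 10_000,
    threshold: float = 10.0,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Stepwise VIF pruning of a raster stack over a seeded cell sample.

    Values are read at a random sample of unmasked cells (all cells if
    fewer are available than requested), making the cost grid-independent.
    Returns the retained layer names and the per-round VIF table.
    """
    names = stack.layer_names
    if len(names) < 2:
        raise ValueError("VIF needs at least 2 layers")
    if sample_cells < 10 * len(names):
        raise ValueError(f"sample_cells must be >= 10 x n_layers = {10 * len(names)}")
    cells = stack.valid_cells()
    rng = np.random.default_rng(seed)
    if cells.size > sample_cells:
        cells = rng.choice(cells, size=sample_cells, replace=False)
    X = stack.to_matrix(names, cells)
    sel = VIFSelector(threshold=threshold).fit(X, feature_names=names)
    return sel.retained_, sel.vif_table_


def build_future_stacks(current: EnvStack, gcm_stacks: list[EnvStack]) -> list[EnvStack]:
    """Combine each GCM's dynamic layers with the current static layers.

    Static layers (e.g. vegetation continuous fields) are assumed constant
    into the future and copied cell-identical from the current stack;
    training bounds are copied from the current stack. Grids must match
    exactly — no silent resampling.
    """
    futures = []
    for gcm in gcm_stacks:
        check_same_grid(current, gcm)
        layers: dict[str, np.ndarray] = {}
        for name in current.layer_names:
            if current.static_flags[name]:
                layers[name] = current.layers[name].copy()
            else:
                if name not in gcm.layers:
                    raise KeyError(f"GCM stack missing dynamic layer {name!r}")
                layers[name] = gcm.layers[name].copy()
        futures.append(
            EnvStack(
                grid=current.grid,
                layers=layers,
                static_flags=dict(current.static_flags),
                train_bounds=dict(current.train_bounds),
            )
        )
    return futures


# ---------------------------------------------------------------------------
# ExDet extrapolation detection
# ---------------------------------------------------------------------------

@dataclass
class ExDetSurface:
    """Univariate (NT1) and combinatorial (NT2) novelty surfaces.

    NT1 <= 0 everywhere; NT1 < 0 iff at least one predictor falls outside
    its reference (training) range, with magnitude the summed proportional
    range extension. NT2 is the Mahalanobis distance to the reference mean
    as a ratio of the maximum Mahalanobis distance within the reference;
    values > 1 flag novel predictor combinations. NT2 is defined only
    where NT1 = 0 (NaN elsewhere). ``most_influential`` holds the index of
    the layer dominating the novelty (-1 where none).
    """

    nt1: np.ndarray
    nt2: np.ndarray
    most_influential: np.ndarray
    layer_names: list[str]


def exdet_arrays(reference: np.ndarray, projection: np.ndarray):
    """ExDet on plain matrices (rows = cells/points, columns = predictors).

    Returns ``(nt1, nt2, most_influential)`` 1-D arrays over projection rows.
    """
    reference = np.asarray(reference, dtype=float)
    projection = np.asarray(projection, dtype=float)
    n_ref, p = reference.shape
    if projection.shape[1] != p:
        raise ValueError("reference and projection have different numbers of predictors")
    if n_ref < p + 2:
        raise ValueError(f"reference needs at least n_layers + 2 = {p + 2} points")

    mins = reference.min(axis=0)
    maxs = reference.max(axis=0)
    widths = maxs - mins
    widths[widths == 0] = np.nan  # constant reference layer: extension undefined

    ud = np.zeros_like(projection)
    below = projection < mins
    above = projection > maxs
    ud = np.where(below, (projection - mins) / widths, ud)
    ud = np.where(above, (maxs - projection) / widths, ud)
    nt1 = np.minimum(ud, 0.0).sum(axis=1)

    nt2 = np.full(projection.shape[0], np.nan)
    mic = np.full(projection.shape[0], -1, dtype=int)

    mean = reference.mean(axis=0)
    cov = np.cov(reference, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        cov_inv = np.linalg.inv(cov)
        singular = False
    except np.linalg.LinAlgError:
        singular = True
    if singular:
        warnings.warn("reference covariance is singular; NT2 masked")
    else:
        d_ref = np.einsum("ij,jk,ik->i", reference - mean, cov_inv, reference - mean)
        d_max = d_ref.max()
        inside = nt1 == 0
        dev = projection[inside] - mean
        d_proj = np.einsum("ij,jk,ik->i", dev, cov_inv, dev)
        nt2[inside] = d_proj / d_max

    # most influential covariate: largest univariate extension where NT1 < 0,
    # largest standardized deviation from the reference mean where NT2 > 1
    out_rows = nt1 < 0
    if out_rows.any():
        mic[out_rows] = np.nanargmin(np.where(np.isnan(ud[out_rows]), 0.0, ud[out_rows]), axis=1)
    if not singular:
        sd = np.sqrt(np.diag(cov))
        novel2 = (nt1 == 0) & (nt2 > 1)
        if novel2.any():
            z = np.abs((projection[novel2] - mean) / sd)
            mic[novel2] = np.argmax(z, axis=1)
    return nt1, nt2, mic


def exdet(
    reference: EnvStack,
    projection: EnvStack,
    reference_cells: np.ndarray | None = None,
) -> ExDetSurface:
    """ExDet novelty surfaces of a projection stack vs. reference conditions.

    ``reference_cells`` restricts the reference to the calibration cells
    (flat indices); defaults to all unmasked reference cells.
    """
    names = reference.layer_names
    if set(names) != set(projection.layer_names):
        raise ValueError(
            f"layer-name mismatch: reference {sorted(names)} vs projection "
            f"{sorted(projection.layer_names)}"
        )
    ref_X = reference.to_matrix(names, reference_cells)
    cells = projection.valid_cells()
    proj_X = projection.to_matrix(names, cells)
    nt1_v, nt2_v, mic_v = exdet_arrays(ref_X, proj_X)

    shape = projection.grid.shape
    nt1 = np.full(shape, np.nan).ravel()
    nt2 = np.full(shape, np.nan).ravel()
    mic = np.full(shape, -1, dtype=int).ravel()
    nt1[cells], nt2[cells], mic[cells] = nt1_v, nt2_v, mic_v
    return ExDetSurface(
        nt1=nt1.reshape(shape),
        nt2=nt2.reshape(shape),
        most_influential=mic.reshape(shape),
        layer_names=names,
    )


def clamp(stack: EnvStack, bounds: dict[str, tuple[float, float]] | None = None) -> EnvStack:
    """Clip every dynamic layer into its training bounds.

    Constrained extrapolation for projections: values outside the range
    seen during calibration are replaced by the nearest bound. Static
    layers are left untouched. Refuses to run if bounds are missing for
    any dynamic layer. Idempotent.
    """
    out = stack.copy()
    if bounds is not None:
        out.train_bounds.update(bounds)
    missing = [n for n in out.dynamic_names if n not in out.train_bounds]
    if missing:
        raise ValueError(f"clamp refused: no training bounds for layers {missing}")
    for name in out.dynamic_names:
        lo, hi = out.train_bounds[name]
        out.layers[name] = np.clip(out.layers[name], lo, hi)
    out.clamped = True
    return out
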