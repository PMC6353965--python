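"""Weighted-average ensemble species distribution models.

A presence-background design: occurrence points are contrasted against
background points sampled from the calibration region. Four member
algorithm families are supported — a MaxEnt-like L1-regularized logistic
model on quadratic features, random forest, gradient-boosted trees, and a
plain (linear) logistic GLM — each producing a suitability score in
[0, 1]. Members are evaluated by 4-fold spatial-block cross-validation
(AUC of the ROC and the True Skill Statistic TSS = max over thresholds of
sensitivity + specificity - 1); the consensus prediction is the weighted
average of member scores with weights proportional to each member's CV
TSS floored at zero. Future projections are made per climate model (on
clamped predictor stacks) and aggregated by the cell-wise median across
climate models.

:class:`EnsembleSDM` follows the scikit-learn estimator protocol
(``fit(X, y)`` / ``predict(X)`` / ``get_params``), so it composes with
sklearn tooling; the raster-facing functions in this module are thin
wrappers that build matrices from stacks and occurrence sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.utils.validation import check_is_fitted

from .calibration import CalibrationRegion, CVBlocks, assign_quadrants, make_blocks
from .grids import EnvStack, check_same_grid
from .occurrences import OccurrenceSet

__all__ = [
    "ALGORITHMS",
    "MIN_PRESENCES",
    "select_algorithms",
    "make_member",
    "auc_score",
    "tss_score",
    "max_tss_threshold",
    "EnsembleSDM",
    "SuitabilitySurface",
    "build_training_data",
    "screen_variables",
    "fit_member",
    "evaluate_cv",
    "consensus_predict",
    "project_future",
    "binarize",
]

ALGORITHMS = ("maxent-like", "random-forest", "boosted-trees", "linear-logistic")

#: Minimum usable number of presences for any model.
MIN_PRESENCES = 5

#: Occurrence-count bands -> member algorithm subset. Data-hungry tree
#: ensembles are dropped for small samples.
DEFAULT_ALGORITHM_BANDS: tuple[tuple[int, tuple[str, ...]], ...] = (
    (30, ALGORITHMS),
    (15, ("maxent-like", "random-forest", "linear-logistic")),
    (MIN_PRESENCES, ("maxent-like", "linear-logistic")),
)


def select_algorithms(n_presences: int, bands=DEFAULT_ALGORITHM_BANDS) -> tuple[str, ...]:
    """Pick the member-algorithm subset for a given occurrence count."""
    for lower, algos in bands:
        if n_presences >= lower:
            return algos
    raise ValueError(f"need at least {MIN_PRESENCES} presences, got {n_presences}")


def make_member(algorithm: str, random_state: int | None = None):
    """Construct an unfitted member estimator producing scores in [0, 1]."""
    if algorithm == "maxent-like":
        return make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=2, include_bias=False),
            LogisticRegression(
                l1_ratio=1.0, solver="liblinear", C=1.0, class_weight="balanced",
                max_iter=500, random_state=random_state,
            ),
        )
    if algorithm == "random-forest":
        return RandomForestClassifier(
            n_estimators=100, min_samples_leaf=2, class_weight="balanced",
            random_state=random_state, n_jobs=1,
        )
    if algorithm == "boosted-trees":
        return HistGradientBoostingClassifier(
            max_iter=100, max_depth=3, class_weight="balanced", random_state=random_state,
        )
    if algorithm == "linear-logistic":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(class_weight="balanced", max_iter=500),
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def auc_score(y_true, scores) -> float:
    """ROC AUC: probability a random presence outscores a random background
    point, ties counting one half."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined for a single class")
    return float(roc_auc_score(y_true, scores))


def tss_score(y_true, scores) -> float:
    """True Skill Statistic: max over thresholds of sensitivity + specificity - 1."""
    fpr, tpr, _ = roc_curve(y_true, scores)
    return float(np.max(tpr - fpr))


def max_tss_threshold(y_true, scores) -> float:
    """The score threshold (cells suitable iff score >= threshold) that
    maximizes TSS; clipped into the observed score range if degenerate."""
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thresholds = roc_curve(y_true, scores)
    i = int(np.argmax(tpr - fpr))
    thr = float(thresholds[i])
    if not np.isfinite(thr) or not 0.0 < thr < 1.0:
        lo, hi = scores.min(), scores.max()
        clipped = float(np.clip(thr, lo, hi))
        warnings.warn(f"max-TSS threshold {thr} outside (0,1); clipped to {clipped}")
        thr = clipped
    return thr


# ---------------------------------------------------------------------------
# variable screening by permutation importance
# ---------------------------------------------------------------------------

def _consensus_scores(members: list, weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    preds = np.column_stack([m.predict_proba(X)[:, 1] for m in members])
    return preds @ weights


def permutation_importance_shares(
    members: list,
    weights: np.ndarray,
    X: np.ndarray,
    n_permutations: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Relative variable contributions (%) to the consensus prediction.

    Importance of a variable is the mean, over ``n_permutations`` shuffles
    of its column, of 1 - Pearson correlation between the original and the
    permuted-prediction; importances are floored at 0 and normalized to
    sum to 100. A variable the consensus ignores scores 0.
    """
    rng = np.random.default_rng(seed)
    base = _consensus_scores(members, weights, X)
    p = X.shape[1]
    raw = np.zeros(p)
    for j in range(p):
        decays = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm = _consensus_scores(members, weights, Xp)
            if np.std(perm) == 0 or np.std(base) == 0:
                decays.append(0.0 if np.allclose(perm, base) else 1.0)
            else:
                decays.append(1.0 - pearsonr(base, perm).statistic)
        raw[j] = max(0.0, float(np.mean(decays)))
    total = raw.sum()
    if total == 0:
        return np.zeros(p)
    return 100.0 * raw / total


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

@dataclass
class _MemberRecord:
    algorithm: str
    estimator: object
    cv_auc: float
    cv_tss: float


class EnsembleSDM(BaseEstimator):
    """Weighted-average consensus of presence-background member models.

    Parameters
    ----------
    algorithms : "auto" or sequence of str
        Member algorithm names; "auto" picks a subset by occurrence count.
    min_contribution : float
        Variable-screening cutoff: predictors whose permutation-importance
        share of the initial all-predictor ensemble is at or below this
        percentage are dropped before the final fit.
    n_permutations : int
        Shuffles per variable for the importance estimate.
    screen : bool
        Whether to run the variable-screening step.
    cap_predictors : bool
        Enforce n_predictors <= n_presences (guards against over-fitting
        for sparsely recorded species).
    random_state : int or None
        Seed for member estimators, screening permutations.

    Attributes (after fit)
    ----------------------
    members_ : list of _MemberRecord  (fitted on all data, retained features)
    weights_ : ndarray, nonnegative, sums to 1 — proportional to CV TSS floored at 0
    importances_ : Series of contribution % per input feature
    retained_predictors_ : list of retained feature names
    support_ : boolean mask over input features
    cv_auc_, cv_tss_ : ensemble-level spatial-CV scores (fold means)
    member_cv_ : DataFrame of per-member CV scores
    threshold_ : max-TSS binarization threshold from pooled out-of-fold
        consensus predictions
    """

    def __init__(
        self,
        algorithms="auto",
        min_contribution: float = 5.0,
        n_permutations: int = 5,
        screen: bool = True,
        cap_predictors: bool = True,
        random_state: int | None = None,
    ):
        self.algorithms = algorithms
        self.min_contribution = min_contribution
        self.n_permutations = n_permutations
        self.screen = screen
        self.cap_predictors = cap_predictors
        self.random_state = random_state

    # -- internals -------------------------------------------------------
    def _resolve_algorithms(self, n_presences: int) -> tuple[str, ...]:
        if self.algorithms == "auto":
            return select_algorithms(n_presences)
        return tuple(self.algorithms)

    def _fit_all(self, algos, X, y):
        fitted = []
        for a in algos:
            est = make_member(a, random_state=self.random_state)
            fitted.append(est.fit(X, y))
        return fitted

    # -- API -------------------------------------------------------------
    def fit(self, X, y, blocks=None, feature_names=None):
        """Fit members with spatial-block CV.

        ``y`` is 1 for presences, 0 for background; ``blocks`` assigns
        every sample (presences and background alike) to a spatial fold id.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        n_pres = int(y.sum())
        if n_pres < MIN_PRESENCES:
            raise ValueError(f"need at least {MIN_PRESENCES} presences, got {n_pres}")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        self.feature_names_in_ = list(feature_names)
        self.n_features_in_ = X.shape[1]
        algos = self._resolve_algorithms(n_pres)
        self.algorithms_ = algos

        # ---- variable screening on an initial all-predictor ensemble ----
        support = np.ones(X.shape[1], dtype=bool)
        if self.screen and X.shape[1] > 1:
            initial = self._fit_all(algos, X, y)
            eq = np.full(len(initial), 1.0 / len(initial))
            shares = permutation_importance_shares(
                initial, eq, X, self.n_permutations,
                seed=self.random_state if self.random_state is not None else 0,
            )
            self.importances_ = pd.Series(shares, index=self.feature_names_in_)
            support = shares > self.min_contribution
            if not support.any():
                warnings.warn(
                    "no predictor exceeded the contribution cutoff; retaining the "
                    "single most important one"
                )
                support[int(np.argmax(shares))] = True
            if self.cap_predictors and support.sum() > n_pres:
                order = np.argsort(shares)  # ascending
                for j in order:
                    if support.sum() <= n_pres:
                        break
                    support[j] = False
        else:
            self.importances_ = pd.Series(
                np.full(X.shape[1], 100.0 / X.shape[1]), index=self.feature_names_in_
            )
            if self.cap_predictors and X.shape[1] > n_pres:
                raise ValueError(
                    f"{X.shape[1]} predictors exceed {n_pres} presences with "
                    "screening disabled"
                )
        self.support_ = support
        self.retained_predictors_ = [n for n, s in zip(self.feature_names_in_, support) if s]
        Xr = X[:, support]

        # ---- spatial-block cross-validation ----
        if blocks is None:
            blocks = np.ones(len(y), dtype=int)
        blocks = np.asarray(blocks)
        fold_ids = np.unique(blocks)
        oof = np.full((len(algos), len(y)), np.nan)
        fold_used = np.zeros(len(y), dtype=bool)
        member_fold_auc: list[list[float]] = [[] for _ in algos]
        member_fold_tss: list[list[float]] = [[] for _ in algos]
        usable_folds = []
        if len(fold_ids) >= 2:
            for b in fold_ids:
                test = blocks == b
                train = ~test
                if y[test].sum() == 0 or (y[test] == 0).sum() == 0:
                    warnings.warn(f"fold {b}: single-class test set skipped")
                    continue
                if len(np.unique(y[train])) < 2:
                    warnings.warn(f"fold {b}: single-class training set skipped")
                    continue
                usable_folds.append(b)
                for k, a in enumerate(algos):
                    est = make_member(a, random_state=self.random_state)
                    est.fit(Xr[train], y[train])
                    s = est.predict_proba(Xr[test])[:, 1]
                    oof[k, test] = s
                    member_fold_auc[k].append(auc_score(y[test], s))
                    member_fold_tss[k].append(tss_score(y[test], s))
                fold_used |= test
        if not usable_folds:
            warnings.warn("no usable CV folds; member weights set equal, scores undefined")
            cv_auc = np.full(len(algos), np.nan)
            cv_tss = np.full(len(algos), np.nan)
            weights = np.full(len(algos), 1.0 / len(algos))
        else:
            cv_auc = np.array([np.mean(v) for v in member_fold_auc])
            cv_tss = np.array([np.mean(v) for v in member_fold_tss])
            floored = np.clip(cv_tss, 0.0, None)
            if floored.sum() == 0:
                warnings.warn("all member CV TSS <= 0; falling back to equal weights")
                weights = np.full(len(algos), 1.0 / len(algos))
            else:
                weights = floored / floored.sum()
        self.weights_ = weights
        self.member_cv_ = pd.DataFrame(
            {"algorithm": algos, "cv_auc": cv_auc, "cv_tss": cv_tss, "weight": weights}
        )

        # ---- ensemble-level CV scores and binarization threshold ----
        if usable_folds:
            ens_auc, ens_tss = [], []
            for b in usable_folds:
                test = blocks == b
                cons = np.nansum(oof[:, test].T * weights, axis=1)
                ens_auc.append(auc_score(y[test], cons))
                ens_tss.append(tss_score(y[test], cons))
            self.cv_auc_ = float(np.mean(ens_auc))
            self.cv_tss_ = float(np.mean(ens_tss))
            pooled = np.einsum("kn,k->n", np.nan_to_num(oof[:, fold_used]), weights)
            self.threshold_ = max_tss_threshold(y[fold_used], pooled)
        else:
            self.cv_auc_ = float("nan")
            self.cv_tss_ = float("nan")

        # ---- final members on all data ----
        fitted = self._fit_all(algos, Xr, y)
        self.members_ = [
            _MemberRecord(a, est, float(cv_auc[k]), float(cv_tss[k]))
            for k, (a, est) in enumerate(zip(algos, fitted))
        ]
        if not hasattr(self, "threshold_"):
            # no CV available: fall back to training predictions
            self.threshold_ = max_tss_threshold(y, self.predict(X[:, support], _validated=True))
        return self

    def predict(self, X, _validated: bool = False) -> np.ndarray:
        """Weighted-average consensus suitability score in [0, 1]."""
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        if not _validated:
            if X.shape[1] == self.n_features_in_:
                X = X[:, self.support_]
            elif X.shape[1] != int(self.support_.sum()):
                raise ValueError(
                    f"X has {X.shape[1]} features; expected {self.n_features_in_} "
                    f"(pre-screening) or {int(self.support_.sum())} (retained)"
                )
        scores = np.column_stack([m.estimator.predict_proba(X)[:, 1] for m in self.members_])
        return scores @ self.weights_

    def predict_range(self, X) -> np.ndarray:
        """Binary range: consensus score >= max-TSS threshold."""
        return self.predict(X) >= self.threshold_


# ---------------------------------------------------------------------------
# raster-facing wrappers
# ---------------------------------------------------------------------------

@dataclass
class SuitabilitySurface:
    """A consensus suitability raster for one species and scenario."""

    species_id: str
    scenario: str
    values: np.ndarray
    threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    def binary_range(self, threshold: float | None = None) -> np.ndarray:
        thr = threshold if threshold is not None else self.threshold
        if thr is None:
            raise ValueError("no binarization threshold available")
        return np.nan_to_num(self.values, nan=-np.inf) >= thr


def build_training_data(
    occ: OccurrenceSet,
    region: CalibrationRegion,
    stack: EnvStack,
    feature_names: list[str] | None = None,
):
    """Assemble (X, y, blocks, blocks_obj) from presences and background.

    Background points are assigned to the same four lon/lat-median spatial
    blocks as the occurrences so folds hold out whole quadrants.
    """
    names = feature_names if feature_names is not None else stack.layer_names
    Xp = stack.values_at(occ.lons, occ.lats, names)
    Xb = stack.to_matrix(names, region.cells)
    keep_p = ~np.isnan(Xp).any(axis=1)
    if not keep_p.all():
        warnings.warn(f"{(~keep_p).sum()} presences fall on masked cells; dropped")
        Xp = Xp[keep_p]
    blocks_obj = make_blocks(occ)
    bp = blocks_obj.assignment[keep_p]
    bb = assign_quadrants(
        region.background["lon"], region.background["lat"],
        blocks_obj.med_lon, blocks_obj.med_lat,
    )
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(len(Xp), dtype=int), np.zeros(len(Xb), dtype=int)])
    blocks = np.concatenate([bp, bb])
    return X, y, blocks, blocks_obj


def screen_variables(
    occ: OccurrenceSet,
    region: CalibrationRegion,
    stack: EnvStack,
    min_contribution: float = 5.0,
    algorithms="auto",
    n_permutations: int = 5,
    seed: int = 0,
) -> tuple[list[str], pd.Series]:
    """Retain predictors contributing more than ``min_contribution`` % to an
    initial all-predictor ensemble (permutation importance), capped at the
    number of occurrences."""
    X, y, blocks, _ = build_training_data(occ, region, stack)
    model = EnsembleSDM(
        algorithms=algorithms,
        min_contribution=min_contribution,
        n_permutations=n_permutations,
        random_state=seed,
    )
    # screening only needs the initial fit; skip CV by passing a single block
    model.fit(X, y, blocks=np.ones(len(y), dtype=int), feature_names=stack.layer_names)
    return model.retained_predictors_, model.importances_


def fit_member(algorithm: str, presences, background, stack: EnvStack, seed: int = 0):
    """Fit one member algorithm on presence/background coordinates."""
    Xp = stack.values_at(presences["lon"], presences["lat"])
    Xb = stack.values_at(background["lon"], background["lat"])
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(len(Xp), dtype=int), np.zeros(len(Xb), dtype=int)])
    if int(y.sum()) < MIN_PRESENCES:
        raise ValueError(f"need at least {MIN_PRESENCES} presences")
    return make_member(algorithm, random_state=seed).fit(X, y)


def evaluate_cv(estimator, X, y, blocks) -> tuple[float, float]:
    """Spatial-block CV of one estimator: mean held-out (AUC, TSS) over folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    blocks = np.asarray(blocks)
    aucs, tsss = [], []
    for b in np.unique(blocks):
        test = blocks == b
        train = ~test
        if y[test].sum() == 0 or (y[test] == 0).sum() == 0 or len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {b} skipped (single-class)")
            continue
        est = clone(estimator)
        est.fit(X[train], y[train])
        s = est.predict_proba(X[test])[:, 1]
        aucs.append(auc_score(y[test], s))
        tsss.append(tss_score(y[test], s))
    if not aucs:
        raise ValueError("no usable CV fold")
    return float(np.mean(aucs)), float(np.mean(tsss))


def consensus_predict(
    ensemble: EnsembleSDM,
    stack: EnvStack,
    species_id: str = "species",
    scenario: str = "current",
    allow_unclamped: bool = False,
) -> SuitabilitySurface:
    """Project the consensus onto a (clamped) predictor stack."""
    check_is_fitted(ensemble, "members_")
    if not stack.clamped and not allow_unclamped:
        raise ValueError(
            "stack has not been clamped to training bounds; apply "
            "sdmrisk.predictors.clamp first or pass allow_unclamped=True"
        )
    cells = stack.valid_cells()
    X = stack.to_matrix(ensemble.retained_predictors_, cells)
    values = np.full(stack.grid.shape, np.nan)
    values.ravel()[cells] = ensemble.predict(X)
    return SuitabilitySurface(
        species_id=species_id,
        scenario=scenario,
        values=values,
        threshold=getattr(ensemble, "threshold_", None),
    )


def project_future(
    ensemble: EnsembleSDM,
    future_stacks: list[EnvStack],
    species_id: str = "species",
    scenario: str = "future",
    allow_unclamped: bool = False,
) -> SuitabilitySurface:
    """Cell-wise median across per-GCM consensus projections.

    Per-GCM surfaces are retained in ``provenance``.
    """
    if not future_stacks:
        raise ValueError("need at least one future stack")
    check_same_grid(*future_stacks)
    per_gcm = [
        consensus_predict(ensemble, s, species_id, scenario, allow_unclamped)
        for s in future_stacks
    ]
    stacked = np.stack([p.values for p in per_gcm])
    median = np.median(stacked, axis=0)
    return SuitabilitySurface(
        species_id=species_id,
        scenario=scenario,
        values=median,
        threshold=getattr(ensemble, "threshold_", None),
        provenance={f"gcm_{i}": p.values for i, p in enumerate(per_gcm)},
    )


def binarize(surface: SuitabilitySurface, threshold: float | None = None) -> np.ndarray:
    """Boolean range raster: suitable iff consensus value >= threshold."""
    return surface.binary_range(threshold)
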