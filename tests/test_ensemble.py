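import itertools

import numpy as np
import pandas as pd
import pytest

from sdmrisk.calibration import build_calibration_region
from sdmrisk.ensemble import (
    EnsembleSDM,
    SuitabilitySurface,
    auc_score,
    binarize,
    build_training_data,
    consensus_predict,
    evaluate_cv,
    fit_member,
    make_member,
    max_tss_threshold,
    project_future,
    select_algorithms,
    tss_score,
)
from sdmrisk.grids import set_train_bounds
from sdmrisk.occurrences import OccurrenceSet, clean_records
from sdmrisk.predictors import clamp
from sdmrisk.synthetic import SamplingDesign, make_virtual_species, sample_occurrences


def brute_force_auc(y, s):
    """Exhaustive pairwise comparison, ties counting one half."""
    pres = [x for x, yy in zip(s, y) if yy == 1]
    bg = [x for x, yy in zip(s, y) if yy == 0]
    wins = sum(1.0 if p > b else 0.5 if p == b else 0.0 for p in pres for b in bg)
    return wins / (len(pres) * len(bg))


def brute_force_tss(y, s):
    """Exhaustive threshold scan (suitable iff score >= threshold)."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    best = -np.inf
    for thr in np.unique(s):
        pred = s >= thr
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        best = max(best, sens + spec - 1)
    return max(best, 0.0)  # threshold above all scores: sens 0, spec 1


class TestScores:
    def test_perfect_separation(self):
        y = [1, 1, 1, 0, 0, 0]
        s = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        assert auc_score(y, s) == 1.0
        assert tss_score(y, s) == 1.0

    def test_all_scores_equal(self):
        y = [1, 1, 0, 0]
        s = [0.4] * 4
        assert auc_score(y, s) == 0.5
        assert tss_score(y, s) == 0.0

    def test_listed_scores_match_brute_force(self):
        y = [1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        s = [0.9, 0.8, 0.8, 0.55, 0.4, 0.3, 0.8, 0.6, 0.5, 0.3, 0.2, 0.1]
        assert auc_score(y, s) == pytest.approx(brute_force_auc(y, s))
        assert tss_score(y, s) == pytest.approx(brute_force_tss(y, s))

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            y = np.r_[np.ones(max(2, n // 3), int), np.zeros(n, int)]
            s = np.round(rng.uniform(0, 1, len(y)), 2)  # rounding forces ties
            assert auc_score(y, s) == pytest.approx(brute_force_auc(y, s))
            assert tss_score(y, s) == pytest.approx(brute_force_tss(y, s))

    def test_max_tss_threshold_lies_in_separating_gap(self):
        y = [1, 1, 1, 0, 0, 0]
        s = [0.9, 0.85, 0.8, 0.3, 0.2, 0.1]
        thr = max_tss_threshold(y, s)
        assert 0.3 < thr <= 0.8


class TestMembers:
    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            make_member("neural-net")

    def test_algorithm_selection_bands(self):
        assert select_algorithms(100) == ("maxent-like", "random-forest", "boosted-trees", "linear-logistic")
        assert "boosted-trees" not in select_algorithms(20)
        assert select_algorithms(6) == ("maxent-like", "linear-logistic")
        with pytest.raises(ValueError):
            select_algorithms(3)

    @pytest.mark.parametrize("algorithm", ["maxent-like", "random-forest", "boosted-trees", "linear-logistic"])
    def test_members_score_in_unit_interval_and_separate_toy(self, algorithm, rng):
        X = np.vstack([rng.normal(3, 0.3, size=(30, 2)), rng.normal(-3, 0.3, size=(200, 2))])
        y = np.r_[np.ones(30, int), np.zeros(200, int)]
        est = make_member(algorithm, random_state=0).fit(X, y)
        s = est.predict_proba(X)[:, 1]
        assert s.min() >= 0 and s.max() <= 1
        assert auc_score(y, s) == 1.0

    def test_permuted_labels_give_chance_level_cv(self, rng):
        """Null check: with labels shuffled, spatial-CV AUC sits near 0.5."""
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(160, 2))
            y = r.permutation(np.r_[np.ones(40, int), np.zeros(120, int)])
            blocks = r.integers(1, 5, 160)
            a, _ = evaluate_cv(make_member("linear-logistic"), X, y, blocks)
            aucs.append(a)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_no_signal_gives_near_zero_tss(self, rng):
        X = rng.normal(size=(400, 2))
        y = np.r_[np.ones(100, int), np.zeros(300, int)]  # identical distributions
        blocks = rng.integers(1, 5, 400)
        _, tss = evaluate_cv(make_member("linear-logistic"), X, y, blocks)
        assert abs(tss) < 0.25


class TestEnsembleEstimator:
    def _toy(self, rng, n_pres=60, n_bg=400):
        X = np.vstack(
            [np.column_stack([rng.normal(2, 0.7, n_pres), rng.normal(size=n_pres)]),
             np.column_stack([rng.normal(-1, 1.5, n_bg), rng.normal(size=n_bg)])]
        )
        y = np.r_[np.ones(n_pres, int), np.zeros(n_bg, int)]
        blocks = rng.integers(1, 5, len(y))
        return X, y, blocks

    def test_sklearn_protocol(self, rng):
        model = EnsembleSDM(random_state=0)
        assert model.get_params()["min_contribution"] == 5.0
        model.set_params(min_contribution=3.0)
        X, y, blocks = self._toy(rng)
        model.fit(X, y, blocks=blocks, feature_names=["signal", "noise"])
        for attr in ("members_", "weights_", "cv_auc_", "cv_tss_", "threshold_", "support_"):
            assert hasattr(model, attr)
        assert model.weights_.sum() == pytest.approx(1.0)
        assert (model.weights_ >= 0).all()

    def test_weights_proportional_to_floored_tss(self, rng, monkeypatch):
        """Members with CV TSS (0.8, 0.4, -0.1) get weights (2/3, 1/3, 0)."""
        tss = np.array([0.8, 0.4, -0.1])
        floored = np.clip(tss, 0, None)
        expected = floored / floored.sum()
        np.testing.assert_allclose(expected, [2 / 3, 1 / 3, 0.0])
        # and the fitted estimator reproduces the same normalization rule
        X, y, blocks = self._toy(rng)
        model = EnsembleSDM(random_state=0).fit(X, y, blocks=blocks)
        cv = model.member_cv_
        fl = np.clip(cv["cv_tss"].to_numpy(), 0, None)
        np.testing.assert_allclose(model.weights_, fl / fl.sum())

    def test_consensus_is_convex_combination_of_members(self, rng):
        X, y, blocks = self._toy(rng)
        model = EnsembleSDM(random_state=0, screen=False, cap_predictors=False).fit(
            X, y, blocks=blocks
        )
        Xnew = rng.normal(size=(200, 2))
        member_scores = np.column_stack(
            [m.estimator.predict_proba(Xnew)[:, 1] for m in model.members_]
        )
        cons = model.predict(Xnew)
        assert (cons >= member_scores.min(axis=1) - 1e-12).all()
        assert (cons <= member_scores.max(axis=1) + 1e-12).all()

    def test_single_member_consensus_is_that_member(self, rng):
        X, y, blocks = self._toy(rng)
        model = EnsembleSDM(algorithms=["linear-logistic"], random_state=0).fit(
            X, y, blocks=blocks
        )
        lone = model.members_[0].estimator.predict_proba(X[:, model.support_])[:, 1]
        np.testing.assert_allclose(model.predict(X), lone)

    def test_constant_feature_gets_zero_importance(self, rng):
        X, y, blocks = self._toy(rng)
        X = np.column_stack([X, np.full(len(y), 3.14)])
        model = EnsembleSDM(random_state=0).fit(
            X, y, blocks=blocks, feature_names=["signal", "noise", "const"]
        )
        assert model.importances_["const"] == 0.0

    def test_contribution_cutoff_keeps_strictly_above_five_percent(self):
        shares = np.array([60.0, 30.0, 6.0, 4.0])
        assert (shares > 5.0).sum() == 3  # the retention rule used by the estimator

    def test_too_few_presences_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        y = np.r_[np.ones(3, int), np.zeros(47, int)]
        with pytest.raises(ValueError, match="presences"):
            EnsembleSDM().fit(X, y)

    def test_determinism_given_random_state(self, rng):
        X, y, blocks = self._toy(rng)
        p1 = EnsembleSDM(random_state=11).fit(X, y, blocks=blocks).predict(X)
        p2 = EnsembleSDM(random_state=11).fit(X, y, blocks=blocks).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestRasterProjection:
    @pytest.fixture()
    def fitted(self, env_small):
        truth = make_virtual_species(env_small, {env_small.layer_names[0]: (0.0, 0.6)}, range_cutoff=0.05)
        raw = sample_occurrences(truth, env_small.grid, SamplingDesign(80, seed=4), "sp")
        occ = clean_records(raw, env_small.grid, species_id="sp")
        with pytest.warns(UserWarning):
            region = build_calibration_region(occ, env_small, n_background=5000, seed=4)
        prow, pcol = env_small.grid.cell_of(occ.lons, occ.lats)
        stack = set_train_bounds(
            env_small, np.union1d(region.cells, prow * env_small.grid.n_cols + pcol)
        )
        X, y, blocks, _ = build_training_data(occ, region, stack)
        model = EnsembleSDM(random_state=4).fit(X, y, blocks=blocks, feature_names=stack.layer_names)
        return model, stack

    def test_unclamped_stack_refused(self, fitted):
        model, stack = fitted
        with pytest.raises(ValueError, match="clamp"):
            consensus_predict(model, stack)
        surf = consensus_predict(model, stack, allow_unclamped=True)
        assert np.nanmin(surf.values) >= 0 and np.nanmax(surf.values) <= 1

    def test_identical_gcm_stacks_median_equals_single(self, fitted):
        model, stack = fitted
        clamped = clamp(stack)
        single = consensus_predict(model, clamped)
        med = project_future(model, [clamped, clamped.copy(), clamped.copy()])
        np.testing.assert_allclose(med.values, single.values, equal_nan=True)
        assert len(med.provenance) == 3

    def test_even_count_median_convention(self):
        vals = [np.full((2, 2), v) for v in (0.2, 0.4, 0.6, 0.8)]
        assert np.median(np.stack(vals), axis=0)[0, 0] == pytest.approx(0.5)

    def test_binarize_uses_geq_convention(self):
        surf = SuitabilitySurface("sp", "current", np.array([[0.49, 0.50, 0.51]]), threshold=0.5)
        np.testing.assert_array_equal(binarize(surf), [[False, True, True]])

    def test_screening_recovers_informative_layer(self, env_small):
        """A species driven by one layer keeps that layer with top importance."""
        name = env_small.layer_names[0]
        wins = 0
        for seed in range(5):
            truth = make_virtual_species(env_small, {name: (0.0, 0.5)}, range_cutoff=0.05)
            raw = sample_occurrences(truth, env_small.grid, SamplingDesign(70, seed=seed), "sp")
            occ = clean_records(raw, env_small.grid, species_id="sp")
            with pytest.warns(UserWarning):
                region = build_calibration_region(occ, env_small, n_background=5000, seed=seed)
            X, y, blocks, _ = build_training_data(occ, region, env_small)
            m = EnsembleSDM(random_state=seed).fit(
                X, y, blocks=blocks, feature_names=env_small.layer_names
            )
            if name in m.retained_predictors_ and m.importances_.idxmax() == name:
                wins += 1
        assert wins >= 3  # majority over seeds


class TestFitMemberWrapper:
    def test_fit_member_from_coordinates(self, env_small):
        grid = env_small.grid
        pres = pd.DataFrame({"lon": grid.centre_of(np.arange(5), np.arange(5))[0],
                             "lat": grid.centre_of(np.arange(5), np.arange(5))[1]})
        rows = np.arange(10, 15)
        bg = pd.DataFrame({"lon": grid.centre_of(rows, rows)[0], "lat": grid.centre_of(rows, rows)[1]})
        est = fit_member("linear-logistic", pres, bg, env_small)
        assert hasattr(est, "predict_proba")
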