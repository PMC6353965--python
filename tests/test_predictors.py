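import numpy as np
import pandas as pd
import pytest

from sdmrisk.grids import EnvStack
from sdmrisk.predictors import (
    VIFSelector,
    build_future_stacks,
    clamp,
    exdet,
    exdet_arrays,
    vif_stepwise,
)


def statsmodels_vif_oracle(X):
    """Independent VIF recomputation through statsmodels OLS."""
    import statsmodels.api as sm

    out = []
    for j in range(X.shape[1]):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out.append(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
    return np.array(out)


class TestVIF:
    def test_independent_layers_all_near_one_nothing_removed(self, rng):
        X = rng.normal(size=(500, 4))
        sel = VIFSelector(threshold=10).fit(X)
        assert sel.support_.all()
        last_round = sel.vif_table_[sel.vif_table_["round"] == sel.vif_table_["round"].max()]
        assert (last_round["vif"] < 2).all()

    def test_exact_duplicate_layer_removed_first_with_infinite_vif(self, rng):
        x = rng.normal(size=500)
        X = np.column_stack([x, x, rng.normal(size=500)])
        sel = VIFSelector(threshold=10).fit(X, feature_names=["a", "a_copy", "b"])
        round1 = sel.vif_table_[sel.vif_table_["round"] == 1]
        assert np.isinf(round1.loc[round1["feature"] == "a", "vif"]).all()
        # tie on infinite VIF broken alphabetically: 'a' removed, 'a_copy' kept
        assert sel.retained_ == ["a_copy", "b"]

    def test_removal_order_matches_least_squares_oracle(self, rng):
        """Stepwise removal replayed with an independent statsmodels R^2 oracle."""
        z = rng.normal(size=(800, 4))
        mixed = 0.95 * (0.6 * z[:, 0] + 0.4 * z[:, 1]) + 0.05 * rng.normal(size=800)
        X = np.column_stack([z, mixed])
        names = ["a", "b", "c", "d", "mix"]
        sel = VIFSelector(threshold=10).fit(X, feature_names=names)

        active = list(range(5))
        removed_order = []
        while len(active) >= 2:
            vifs = statsmodels_vif_oracle(X[:, active])
            worst = vifs.max()
            if worst <= 10:
                break
            cand = [k for k in range(len(active)) if np.isclose(vifs[k], worst) or (np.isinf(vifs[k]) and np.isinf(worst))]
            pick = min(cand, key=lambda k: names[active[k]])
            removed_order.append(names[active[pick]])
            del active[pick]
        expected_retained = [names[i] for i in active]
        assert sel.retained_ == expected_retained
        got_removed = sel.vif_table_.loc[sel.vif_table_["removed"], "feature"].tolist()
        assert got_removed == removed_order
        # final VIF values agree with the oracle
        final = sel.vif_table_[sel.vif_table_["round"] == sel.vif_table_["round"].max()]
        np.testing.assert_allclose(
            final["vif"].to_numpy(), statsmodels_vif_oracle(X[:, active]), rtol=1e-6
        )

    def test_terminates_and_order_invariant_without_ties(self, rng):
        z = rng.normal(size=(600, 3))
        X = np.column_stack([z, z[:, 0] * 0.97 + 0.03 * rng.normal(size=600)])
        names = ["a", "b", "c", "d"]
        sel1 = VIFSelector().fit(X, feature_names=names)
        perm = [2, 0, 3, 1]
        sel2 = VIFSelector().fit(X[:, perm], feature_names=[names[i] for i in perm])
        assert set(sel1.retained_) == set(sel2.retained_)
        assert sel1.vif_table_["round"].max() <= X.shape[1] - 1

    def test_stack_level_wrapper_samples_cells(self, env_small):
        retained, table = vif_stepwise(env_small, sample_cells=30, threshold=10, seed=0)
        assert set(retained) <= set(env_small.layer_names)
        assert {"round", "feature", "vif", "removed"} <= set(table.columns)

    def test_sample_size_floor_enforced(self, env_small):
        with pytest.raises(ValueError, match="10 x n_layers"):
            vif_stepwise(env_small, sample_cells=20, threshold=10)


class TestFutureStackAssembly:
    def test_static_only_stack_future_equals_current(self, small_grid, rng):
        cur = EnvStack(
            small_grid,
            {"vcf": rng.normal(size=small_grid.shape)},
            static_flags={"vcf": True},
        )
        gcm = EnvStack(small_grid, {"ignored": rng.normal(size=small_grid.shape)})
        futures = build_future_stacks(cur, [gcm])
        np.testing.assert_array_equal(futures[0].layers["vcf"], cur.layers["vcf"])

    def test_four_gcms_in_four_out_order_preserved(self, env_small, rng):
        gcms = [
            EnvStack(env_small.grid, {n: env_small.layers[n] + k for n in env_small.layer_names})
            for k in range(4)
        ]
        futures = build_future_stacks(env_small, gcms)
        assert len(futures) == 4
        name = env_small.layer_names[0]
        for k in range(4):
            np.testing.assert_allclose(futures[k].layers[name], env_small.layers[name] + k)

    def test_static_vcf_cell_identical_and_bounds_copied(self, small_grid, rng):
        cur = EnvStack(
            small_grid,
            {"temp": rng.normal(size=small_grid.shape), "vcf": rng.uniform(size=small_grid.shape)},
            static_flags={"vcf": True},
            train_bounds={"temp": (-1.0, 1.0), "vcf": (0.0, 1.0)},
        )
        gcm = EnvStack(small_grid, {"temp": rng.normal(size=small_grid.shape) + 2})
        fut = build_future_stacks(cur, [gcm])[0]
        np.testing.assert_array_equal(fut.layers["vcf"], cur.layers["vcf"])
        assert fut.train_bounds == cur.train_bounds

    def test_missing_dynamic_layer_rejected(self, small_grid, rng):
        cur = EnvStack(small_grid, {"temp": rng.normal(size=small_grid.shape)})
        gcm = EnvStack(small_grid, {"prec": rng.normal(size=small_grid.shape)})
        with pytest.raises(KeyError, match="temp"):
            build_future_stacks(cur, [gcm])


class TestExDet:
    def test_reference_centroid_inside_ranges_scores_zero(self, rng):
        ref = rng.normal(size=(50, 3))
        centroid = ref.mean(axis=0, keepdims=True)
        nt1, nt2, _ = exdet_arrays(ref, centroid)
        assert nt1[0] == 0.0
        assert nt2[0] == pytest.approx(0.0, abs=1e-12)

    def test_one_range_width_below_min_gives_nt1_minus_one(self):
        ref = np.column_stack([np.linspace(0, 1, 10), np.linspace(5, 6, 10)])
        proj = np.array([[-1.0, 5.5]])  # one full range-width below min of layer 0
        nt1, nt2, mic = exdet_arrays(ref, proj)
        assert nt1[0] == pytest.approx(-1.0)
        assert np.isnan(nt2[0])  # NT2 undefined where NT1 < 0
        assert mic[0] == 0

    def test_nt2_matches_hand_computed_mahalanobis_on_toy(self):
        """5-point, 2-layer toy vs an explicit inverse-covariance oracle."""
        ref = np.array([[0.0, 0.0], [1.0, 0.2], [2.0, -0.1], [3.0, 0.3], [4.0, 0.0]])
        proj = np.array([[2.0, 0.1], [1.5, 0.25], [3.5, -0.05]])
        nt1, nt2, _ = exdet_arrays(ref, proj)
        mean = ref.mean(axis=0)
        cov_inv = np.linalg.inv(np.cov(ref, rowvar=False, ddof=1))
        d2_ref = [(r - mean) @ cov_inv @ (r - mean) for r in ref]
        expected = [(p - mean) @ cov_inv @ (p - mean) / max(d2_ref) for p in proj]
        np.testing.assert_allclose(nt1, 0.0)
        np.testing.assert_allclose(nt2, expected, rtol=1e-12)

    def test_nt1_nonpositive_and_negative_iff_outside(self, rng):
        ref = rng.normal(size=(100, 3))
        proj = rng.normal(size=(400, 3)) * 2.0
        nt1, _, _ = exdet_arrays(ref, proj)
        assert (nt1 <= 0).all()
        outside = ((proj < ref.min(0)) | (proj > ref.max(0))).any(axis=1)
        np.testing.assert_array_equal(nt1 < 0, outside)

    def test_stack_interface_checks_layer_names(self, env_small):
        other = EnvStack(env_small.grid, {"zzz": np.ones(env_small.grid.shape)})
        with pytest.raises(ValueError, match="mismatch"):
            exdet(env_small, other)


class TestClamp:
    def _bounded(self, env):
        out = env.copy()
        for n in out.layer_names:
            out.train_bounds[n] = (-0.5, 0.5)
        return out

    def test_values_clipped_into_training_bounds(self, env_small):
        clamped = clamp(self._bounded(env_small))
        for n in clamped.dynamic_names:
            vals = clamped.layers[n]
            assert np.nanmin(vals) >= -0.5 and np.nanmax(vals) <= 0.5
        assert clamped.clamped

    def test_idempotent(self, env_small):
        once = clamp(self._bounded(env_small))
        twice = clamp(once)
        for n in once.layer_names:
            np.testing.assert_array_equal(once.layers[n], twice.layers[n])

    def test_within_bounds_is_identity(self, env_small):
        out = env_small.copy()
        for n in out.layer_names:
            out.train_bounds[n] = (-100.0, 100.0)
        clamped = clamp(out)
        for n in out.layer_names:
            np.testing.assert_array_equal(clamped.layers[n], env_small.layers[n])

    def test_missing_bounds_refused(self, env_small):
        with pytest.raises(ValueError, match="refused"):
            clamp(env_small)

    def test_static_layers_untouched(self, env_small):
        out = self._bounded(env_small)
        static = out.layer_names[0]
        out.static_flags[static] = True
        clamped = clamp(out)
        np.testing.assert_array_equal(clamped.layers[static], out.layers[static])
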