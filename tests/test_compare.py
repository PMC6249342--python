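"""Permutation inference: p-value mechanics, AUC/FDA summaries, nodal
comparison, and hub set arithmetic."""

import numpy as np
import pandas as pd
import pytest

import covnet
from covnet.compare import (PermutationConfig, auc_summary, fda_summary,
                            percentile_p)
from covnet.metrics import HubSet


def _two_group_frame(Y_a, Y_b):
    p = Y_a.shape[1]
    cols = [f"ROI_{j:03d}" for j in range(p)]
    df = pd.DataFrame(np.vstack([Y_a, Y_b]), columns=cols)
    df.insert(0, "group", ["A"] * len(Y_a) + ["B"] * len(Y_b))
    df.insert(0, "subject_id", [f"s{i}" for i in range(len(df))])
    return df


class TestPercentileP:
    def test_observed_beyond_all_nulls_gives_floor(self):
        null = np.arange(99, dtype=float)
        assert percentile_p(1000.0, null) == pytest.approx(2 / 100)

    def test_central_observation_capped_at_one(self):
        null = np.concatenate([np.arange(50), np.arange(50)]).astype(float)
        assert percentile_p(np.median(null), null) == 1.0

    def test_never_zero_or_negative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            null = rng.standard_normal(200)
            p = percentile_p(float(rng.standard_normal()), null)
            assert 0 < p <= 1

    def test_symmetric_two_tailed(self):
        null = np.linspace(-1, 1, 201)
        assert percentile_p(0.9, null) == pytest.approx(percentile_p(-0.9, null))

    def test_nan_null_entries_dropped(self):
        null = np.array([0.0, 1.0, np.nan, 2.0])
        assert np.isfinite(percentile_p(1.5, null))


class TestAucFda:
    def test_constant_difference_integral(self):
        grid = np.round(np.arange(0.10, 0.51, 0.02), 2)
        d = 0.7
        obs = np.full(len(grid), d)
        null = np.zeros((50, len(grid)))
        stat, _ = auc_summary(grid, obs, null)
        assert stat == pytest.approx(0.4 * d)

    def test_antisymmetric_difference_integrates_to_zero(self):
        grid = np.linspace(0.1, 0.5, 21)
        obs = np.linspace(-1, 1, 21)
        stat, _ = auc_summary(grid, obs, np.zeros((10, 21)))
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_matches_composite_trapezoid_oracle(self):
        rng = np.random.default_rng(1)
        grid = np.sort(rng.uniform(0.1, 0.5, 9))
        obs = rng.standard_normal(9)
        stat, _ = auc_summary(grid, obs, rng.standard_normal((20, 9)))
        oracle = sum((obs[i] + obs[i + 1]) / 2 * (grid[i + 1] - grid[i])
                     for i in range(8))
        assert stat == pytest.approx(oracle, abs=1e-12)

    def test_identical_curves_fda(self):
        grid = np.array([0.1, 0.2, 0.3])
        obs = np.zeros(3)
        null = np.random.default_rng(2).standard_normal((100, 3))
        stat, p = fda_summary(grid, obs, null)
        assert stat == 0.0
        assert p > 0.5

    def test_single_density_fda_is_pointwise_difference(self):
        grid = np.array([0.3])
        stat, _ = fda_summary(grid, np.array([0.42]), np.zeros((10, 1)))
        assert stat == pytest.approx(0.42)

    def test_mismatched_grid_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            auc_summary(np.array([0.1, 0.2]), np.zeros(3), np.zeros((5, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            fda_summary(np.array([0.1, 0.2]), np.zeros(2), np.zeros((5, 3)))

    def test_auc_needs_two_densities(self):
        with pytest.raises(ValueError, match=">= 2"):
            auc_summary(np.array([0.1]), np.zeros(1), np.zeros((5, 1)))


class TestGlobalPermutation:
    def test_identical_groups_zero_difference(self, rng):
        Y = rng.standard_normal((20, 30))
        df = _two_group_frame(Y, Y.copy())  # group B duplicates group A
        cfg = PermutationConfig(n_permutations=100,
                                densities=np.array([0.2, 0.3, 0.4]),
                                measures=("Q",), seed=5)
        res = covnet.permutation_test_global(df, cfg)["Q"]
        np.testing.assert_allclose(res.observed, 0.0, atol=1e-12)
        assert np.all(res.p_by_density >= cfg.alpha)
        assert res.fda_p >= cfg.alpha

    def test_seed_determinism(self, small_residuals):
        cfg = PermutationConfig(n_permutations=100,
                                densities=np.array([0.2, 0.3]),
                                measures=("Q",), seed=9)
        r1 = covnet.permutation_test_global(small_residuals, cfg)["Q"]
        r2 = covnet.permutation_test_global(small_residuals, cfg)["Q"]
        np.testing.assert_array_equal(r1.p_by_density, r2.p_by_density)
        assert r1.auc_p == r2.auc_p and r1.fda_p == r2.fda_p

    def test_ci_band_consistent_with_p(self, small_residuals):
        """Observed difference outside the 2.5-97.5 percentile band iff
        two-tailed p < 0.05, up to the +1 correction at the boundary."""
        cfg = PermutationConfig(n_permutations=200,
                                densities=np.array([0.15, 0.25, 0.35, 0.45]),
                                measures=("Q", "C"), seed=3)
        results = covnet.permutation_test_global(small_residuals, cfg)
        slack = 2 / (cfg.n_permutations + 1)
        for res in results.values():
            outside = ((res.observed < res.ci_low)
                       | (res.observed > res.ci_high))
            for i in range(len(res.densities)):
                if res.p_by_density[i] < 0.05 - slack:
                    assert outside[i]
                elif res.p_by_density[i] > 0.05 + slack:
                    assert not outside[i]

    def test_multiple_measures_returned(self, small_residuals):
        cfg = PermutationConfig(n_permutations=100,
                                densities=np.array([0.2, 0.3]),
                                measures=("C", "L", "Q"), seed=1)
        results = covnet.permutation_test_global(small_residuals, cfg)
        assert set(results) == {"C", "L", "Q"}
        for res in results.values():
            assert res.to_frame().shape[0] == 2

    def test_normalized_measures_through_permutation(self, rng):
        """gamma/lambda/sigma rebuild a null rewiring ensemble inside each
        permutation; sigma must equal gamma/lambda on every curve."""
        Y = rng.standard_normal((24, 15))
        df = _two_group_frame(Y[:12], Y[12:])
        cfg = PermutationConfig(n_permutations=100,
                                densities=np.array([0.3]),
                                measures=("gamma", "lambda", "sigma"),
                                n_null=2, seed=8)
        results = covnet.permutation_test_global(df, cfg)
        assert set(results) == {"gamma", "lambda", "sigma"}
        g, l, s = (results[m] for m in ("gamma", "lambda", "sigma"))
        for curves in ("curve_a", "curve_b"):
            np.testing.assert_allclose(
                getattr(s, curves),
                getattr(g, curves) / getattr(l, curves), atol=1e-12)
        for res in results.values():
            assert np.isfinite(res.observed).all()
            assert 0 < res.fda_p <= 1

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_permutations"):
            PermutationConfig(n_permutations=50).validate()
        with pytest.raises(ValueError, match="alpha"):
            PermutationConfig(alpha=1.5).validate()
        with pytest.raises(ValueError, match="unknown measures"):
            PermutationConfig(measures=("Z",)).validate()

    def test_planted_difference_detected(self):
        """Loading gap 0.45 vs 0.75 at n=30/group: modularity FDA p small."""
        table, _ = covnet.generate_cohort(
            covnet.CohortSpec(seed=100, within_loading_by_group=(0.45, 0.75)))
        resid = covnet.residualize(table)
        cfg = PermutationConfig(
            n_permutations=200,
            densities=np.round(np.arange(0.10, 0.51, 0.08), 2),
            measures=("Q",), seed=0)
        res = covnet.permutation_test_global(resid, cfg)["Q"]
        assert res.fda_p < 0.05
        assert res.observed.mean() < 0  # group B (stronger loading) higher Q


class TestNodalPermutation:
    def test_identical_groups_nothing_significant(self, rng):
        Y = rng.standard_normal((20, 30))
        df = _two_group_frame(Y, Y.copy())
        cfg = PermutationConfig(n_permutations=100,
                                densities=np.array([0.3]), seed=2)
        res = covnet.permutation_test_nodal(df, cfg, density=0.3)
        np.testing.assert_allclose(res.frame["difference"], 0.0, atol=1e-12)
        assert res.significant_nodes == []

    def test_reference_density_defaults_to_min_common_connected(
            self, small_residuals):
        grid = covnet.default_density_grid()
        cfg = PermutationConfig(n_permutations=100, densities=grid, seed=2)
        expected = covnet.reference_density(small_residuals, grid)
        res = covnet.permutation_test_nodal(small_residuals, cfg)
        assert res.density == expected
        assert len(res.frame) == 90

    def test_bridge_node_detected(self):
        """A node that bridges two modules in group A only loses normalized
        betweenness in group B."""
        rng = np.random.default_rng(7)
        n, p = 100, 21
        bridge = p - 1
        noise = 0.4

        def make_group(bridging):
            f = rng.standard_normal((n, 2))
            pair = rng.standard_normal((n, 4))
            Y = np.empty((n, p))
            Y[:, :10] = f[:, [0]] + rng.standard_normal((n, 10)) * noise
            Y[:, 10:20] = f[:, [1]] + rng.standard_normal((n, 10)) * noise
            # permanent cross links (k, 10+k) in BOTH groups keep the
            # betweenness landscape graded (no sole-connector degeneracy)
            for k in range(4):
                Y[:, k] += 0.8 * pair[:, k]
                Y[:, 10 + k] += 0.8 * pair[:, k]
            if bridging:
                Y[:, bridge] = (0.6 * (f[:, 0] + f[:, 1])
                                + rng.standard_normal(n) * 0.6)
            else:
                Y[:, bridge] = rng.standard_normal(n)
            return Y

        df = _two_group_frame(make_group(True), make_group(False))
        cfg = PermutationConfig(n_permutations=300, densities=np.array([0.5]),
                                seed=4)
        res = covnet.permutation_test_nodal(df, cfg, density=0.5)
        row = res.frame.iloc[bridge]
        assert row["difference"] > 0  # bridge more central in group A
        assert row["p"] < 0.05


class TestCompareHubs:
    def _hub(self, members, universe=None):
        universe = universe or [f"n{i}" for i in range(40)]
        return HubSet(list(members), 1.0, universe)

    def test_identical_sets_all_shared(self):
        h = self._hub(["n1", "n2", "n3"])
        cmp = covnet.compare_hubs(h, self._hub(["n1", "n2", "n3"]))
        assert cmp.shared == ["n1", "n2", "n3"]
        assert cmp.only_a == cmp.only_b == []

    def test_disjoint_sets(self):
        a = self._hub([f"n{i}" for i in range(15)])
        b = self._hub([f"n{i}" for i in range(15, 32)])
        cmp = covnet.compare_hubs(a, b)
        assert cmp.shared == []
        assert len(cmp.only_a) == 15 and len(cmp.only_b) == 17

    def test_overlap_of_three(self):
        a = self._hub(["n0", "n1", "n2", "n3", "n4"])
        b = self._hub(["n2", "n3", "n4", "n10"])
        cmp = covnet.compare_hubs(a, b)
        assert cmp.shared == ["n2", "n3", "n4"]

    def test_universe_mismatch_rejected(self):
        a = self._hub(["n1"])
        b = HubSet(["x1"], 1.0, [f"x{i}" for i in range(40)])
        with pytest.raises(ValueError, match="universe"):
            covnet.compare_hubs(a, b)
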