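"""Soft power, TOM, module detection, eigengenes, merging, trait association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from sysgen import (ModuleSet, cluster_modules, compute_eigengenes,
                    hard_threshold_edges, merge_modules, module_eigengene,
                    module_trait_association, pick_soft_power, tom_similarity)
from sysgen.network import adjacency_matrix


def planted_blocks(sizes, loading, n_lines=96, seed=0, n_noise=0):
    """Latent-factor block data: x = loading*z_block + sqrt(1-loading^2)*eps."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for b, size in enumerate(sizes, start=1):
        z = rng.standard_normal(n_lines)
        for _ in range(size):
            rows.append(loading * z
                        + np.sqrt(1 - loading ** 2) * rng.standard_normal(n_lines))
            truth.append(b)
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_lines))
        truth.append(0)
    names = [f"t{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=names), np.array(truth)


class TestSoftPower:
    def test_hub_structure_reaches_fit(self):
        values, _ = planted_blocks([60, 50, 40], 0.8, seed=1, n_noise=150)
        report = pick_soft_power(values)
        assert report.chosen_fit >= 0.8
        assert 1 <= report.chosen <= 20

    def test_noise_at_beta_one_has_poor_fit(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.standard_normal((200, 60)))
        report = pick_soft_power(values)
        fit_b1 = report.table.loc[report.table["power"] == 1, "fit"].iloc[0]
        assert fit_b1 < 0.5      # homogeneous connectivity: no power law at beta=1

    def test_too_few_transcripts_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            pick_soft_power(pd.DataFrame(rng.standard_normal((2, 20))))

    def test_mean_connectivity_decreases_with_power(self):
        values, _ = planted_blocks([50, 50], 0.7, seed=4)
        report = pick_soft_power(values)
        k = report.table["mean_k"].to_numpy()
        assert np.all(np.diff(k) < 0)


class TestTOM:
    def test_all_zero_adjacency_gives_identity(self):
        omega = tom_similarity(np.zeros((4, 4)))
        np.testing.assert_allclose(omega, np.eye(4))

    def test_three_node_half_adjacency_hand_value(self):
        # l_ij = 0.25, a = 0.5, min k = 1: (0.25+0.5)/(1+1-0.5) = 0.5
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 0.0)
        omega = tom_similarity(A)
        expected = np.full((3, 3), 0.5)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(omega, expected, atol=1e-12)

    def test_single_strong_edge_hand_value(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        omega = tom_similarity(A)
        assert omega[0, 1] == pytest.approx(1.0)   # (0+1)/(1+1-1)
        assert omega[0, 2] == pytest.approx(0.0)

    def test_asymmetric_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(A)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, derandomize=True)
    def test_tom_bounds_symmetry_unit_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        A = rng.random((n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        omega = tom_similarity(A)
        assert np.all((omega >= 0) & (omega <= 1))
        np.testing.assert_allclose(omega, omega.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(omega), 1.0)


class TestClusterModules:
    def test_two_planted_blocks_recovered_exactly(self):
        values, truth = planted_blocks([50, 50], 0.8, seed=5)
        # between-block correlation ~0, within ~0.64
        A, idx = adjacency_matrix(values, 6)
        modules = cluster_modules(tom_similarity(A), idx, min_size=30)
        assert len(modules.labels) == 2
        assert adjusted_rand_score(truth, modules.membership.to_numpy()) == 1.0

    def test_pure_noise_mostly_unassigned(self):
        unassigned_ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            values = pd.DataFrame(rng.standard_normal((100, 60)),
                                  index=[f"t{i}" for i in range(100)])
            A, idx = adjacency_matrix(values, 6)
            modules = cluster_modules(tom_similarity(A), idx, min_size=30)
            if (modules.membership == 0).mean() >= 0.9:
                unassigned_ok += 1
        assert unassigned_ok >= 9

    def test_block_below_min_size_unassigned(self):
        values, _ = planted_blocks([29], 0.8, seed=6, n_noise=40)
        A, idx = adjacency_matrix(values, 6)
        modules = cluster_modules(tom_similarity(A), idx, min_size=30)
        planted = modules.membership.iloc[:29]
        assert (planted == 0).all()


class TestEigengene:
    def test_identical_transcripts_give_common_profile(self):
        rng = np.random.default_rng(7)
        profile = rng.standard_normal(40)
        values = pd.DataFrame([profile] * 5, index=[f"t{i}" for i in range(5)],
                              columns=[f"L{i}" for i in range(40)])
        me = module_eigengene(values)
        z = (profile - profile.mean()) / profile.std()
        ratio = me.to_numpy() / (z / z.std(ddof=0) * z.std(ddof=0))
        corr = np.corrcoef(me, profile)[0, 1]
        assert corr == pytest.approx(1.0)
        assert me.std(ddof=1) == pytest.approx(1.0)

    def test_antisymmetric_pair_uses_first_member_fallback(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30)
        values = pd.DataFrame([x, -x], index=["a", "b"],
                              columns=[f"L{i}" for i in range(30)])
        me = module_eigengene(values)
        assert np.corrcoef(me, x)[0, 1] > 0    # oriented to the first member

    def test_variance_maximality_against_random_combinations(self):
        rng = np.random.default_rng(9)
        values = pd.DataFrame(rng.standard_normal((30, 96)),
                              index=[f"t{i}" for i in range(30)])
        Z = values.sub(values.mean(axis=1), axis=0).div(values.std(axis=1), axis=0)
        me = module_eigengene(values).to_numpy()
        me_u = me / np.linalg.norm(me)
        explained_me = np.sum((Z.to_numpy() @ me_u) ** 2)
        W = rng.standard_normal((10_000, 96))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        explained_random = np.sum((Z.to_numpy() @ W.T) ** 2, axis=0)
        assert explained_me >= explained_random.max()


class TestMergeModules:
    def _set_from_truth(self, values, truth):
        ms = ModuleSet(pd.Series(truth, index=values.index))
        ms.eigengenes = compute_eigengenes(values, ms)
        return ms

    def test_high_similarity_pair_merges(self):
        rng = np.random.default_rng(10)
        z = rng.standard_normal(60)
        rows = [0.9 * z + 0.44 * rng.standard_normal(60) for _ in range(60)]
        values = pd.DataFrame(rows, index=[f"t{i}" for i in range(60)])
        truth = np.array([1] * 30 + [2] * 30)
        merged = merge_modules(values, self._set_from_truth(values, truth))
        assert len(merged.labels) == 1
        assert len(merged.merge_history) == 1

    def test_dissimilar_modules_untouched(self):
        values, truth = planted_blocks([40, 40], 0.8, seed=11)
        merged = merge_modules(values, self._set_from_truth(values, truth + 0))
        assert len(merged.labels) == 2
        assert merged.merge_history == []

    def test_chained_merge_via_recomputation(self):
        # three modules with latent correlations (0.9, 0.9, 0.65): only one
        # pair exceeds the cut at first, but after that merge the recomputed
        # eigengene pulls the third module above the cut, chaining all three
        rng = np.random.default_rng(12)
        n = 80
        cov = np.array([[1.0, 0.9, 0.65], [0.9, 1.0, 0.9], [0.65, 0.9, 1.0]])
        z = rng.multivariate_normal(np.zeros(3), cov, size=n).T
        rows, truth = [], []
        for b in range(3):
            for _ in range(30):
                rows.append(0.97 * z[b]
                            + np.sqrt(1 - 0.97 ** 2) * rng.standard_normal(n))
                truth.append(b + 1)
        values = pd.DataFrame(rows, index=[f"t{i}" for i in range(90)])
        pre = self._set_from_truth(values, np.array(truth))
        corr0 = pre.eigengenes.corr().to_numpy()
        assert corr0[0, 2] < 0.75      # 1-3 not mergeable directly
        merged = merge_modules(values, pre, similarity_cut=0.75)
        assert len(merged.labels) == 1
        assert len(merged.merge_history) == 2

    def test_final_similarity_below_cut(self):
        values, truth = planted_blocks([40, 40, 40], 0.7, seed=13)
        merged = merge_modules(values, self._set_from_truth(values, truth))
        corr = merged.eigengenes.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.75


class TestModuleTraitAssociation:
    def _modules_with_me(self, seed=14):
        values, truth = planted_blocks([40, 40], 0.8, seed=seed)
        ms = ModuleSet(pd.Series(truth, index=values.index))
        ms.eigengenes = compute_eigengenes(values, ms)
        ms.eigengenes.index = [f"L{i}" for i in range(len(ms.eigengenes))]
        return ms

    def test_trait_equal_to_me(self):
        ms = self._modules_with_me()
        traits = pd.DataFrame({"lignin": ms.eigengenes[1]})
        out = module_trait_association(ms.eigengenes, traits)
        row = out[(out["module"] == 1) & (out["trait"] == "lignin")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-50

    def test_independent_trait_weak_correlation(self):
        hits = 0
        for seed in range(20):
            ms = self._modules_with_me(seed=20 + seed)
            rng = np.random.default_rng(seed)
            traits = pd.DataFrame({"x": rng.standard_normal(len(ms.eigengenes))},
                                  index=ms.eigengenes.index)
            out = module_trait_association(ms.eigengenes, traits)
            if out["r"].abs().max() < 0.3:
                hits += 1
        assert hits >= 19

    def test_planted_r_recovered(self):
        # population |r| = 0.8 (the magnitude of a strong module-trait link)
        hits = 0
        for seed in range(20):
            ms = self._modules_with_me(seed=50 + seed)
            rng = np.random.default_rng(seed)
            me = ms.eigengenes[1]
            trait = 0.8 * me + 0.6 * rng.standard_normal(len(me))
            traits = pd.DataFrame({"lignin": trait}, index=me.index)
            out = module_trait_association(ms.eigengenes, traits)
            r = out[(out["module"] == 1)]["r"].iloc[0]
            if 0.7 <= r <= 0.9:
                hits += 1
        assert hits >= 18

    def test_constant_trait_reported_missing(self):
        ms = self._modules_with_me()
        traits = pd.DataFrame({"flat": np.ones(len(ms.eigengenes))},
                              index=ms.eigengenes.index)
        out = module_trait_association(ms.eigengenes, traits)
        assert out["r"].isna().all()


class TestHardThresholdEdges:
    def test_uncorrelated_data_no_edges(self):
        rng = np.random.default_rng(15)
        values = pd.DataFrame(rng.standard_normal((30, 400)))
        assert len(hard_threshold_edges(values, cut=0.75)) == 0

    def test_negative_correlation_included_by_absolute_value(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(50)
        values = pd.DataFrame([x, -x + 0.1 * rng.standard_normal(50)],
                              index=["up", "down"])
        edges = hard_threshold_edges(values, cut=0.75)
        assert len(edges) == 1
        assert edges["r"].iloc[0] < 0

    def test_planted_blocks_give_only_within_block_edges(self):
        values, truth = planted_blocks([20, 20, 20], 0.95, seed=17)
        edges = hard_threshold_edges(values, cut=0.75)
        assert len(edges) > 0
        block = pd.Series(truth, index=values.index)
        cross = sum(block[a] != block[b]
                    for a, b in zip(edges["node_a"], edges["node_b"]))
        assert cross == 0


class TestEndToEndModuleRecovery:
    def test_planted_three_module_ari(self):
        """Tree cut + merge recovers 3 planted modules at high ARI."""
        passed = 0
        for seed in range(5):
            values, truth = planted_blocks([50, 80, 120], 0.8, seed=60 + seed,
                                           n_noise=0)
            A, idx = adjacency_matrix(values, 6)
            modules = cluster_modules(tom_similarity(A), idx, min_size=30)
            modules.eigengenes = compute_eigengenes(values, modules)
            modules = merge_modules(values, modules)
            ari = adjusted_rand_score(truth, modules.membership.to_numpy())
            if ari >= 0.9:
                passed += 1
        assert passed == 5
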