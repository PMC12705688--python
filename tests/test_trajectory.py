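"""Smoothing, pseudotime, state segmentation, gene programs, markers."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chronotrace.simulate import SimulationConfig, simulate_timeseries
from chronotrace.timeprop import build_neighbor_graph, concordance, pca_embedding
from chronotrace.trajectory import (
    cluster_genes,
    cluster_profiles,
    compute_pseudotime,
    find_markers,
    intersect_maturity_sets,
    label_maturity,
    normalize_log1p_cp10k,
    segment_states,
    smooth_expression,
    velocity_speed,
)


class TestSmoothExpression:
    def test_zero_neighbors_is_identity(self):
        X = np.arange(12, dtype=float).reshape(4, 3)
        out = smooth_expression(X, np.empty((4, 0), dtype=int))
        np.testing.assert_array_equal(out, X)

    def test_two_identical_cells_unchanged(self):
        X = np.array([[2.0, 5.0], [2.0, 5.0]])
        out = smooth_expression(X, np.array([[1], [0]]))
        np.testing.assert_allclose(out, X)

    def test_three_cell_chain_hand_oracle(self):
        # values 0, 3, 6 on a line; k=1 with index tie-break: the middle
        # cell averages with cell 0 (equidistant tie), ends with the middle
        emb = np.array([[0.0], [1.0], [2.0]])
        g = build_neighbor_graph(emb, k=1, exclude_self=True)
        X = np.array([[0.0], [3.0], [6.0]])
        out = smooth_expression(X, g.indices)
        np.testing.assert_allclose(out.ravel(), [1.5, 1.5, 4.5])

    def test_preserves_global_mean_on_regular_graph(self):
        # symmetric neighbor structure: smoothing redistributes but keeps
        # the per-gene mean (doubly stochastic averaging)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        ring = np.array([[(i - 1) % 6, (i + 1) % 6] for i in range(6)])
        out = smooth_expression(X, ring)
        np.testing.assert_allclose(out.mean(axis=0), X.mean(axis=0), atol=1e-12)


class TestComputePseudotime:
    def test_chain_is_monotone_and_root_zero(self):
        # cells along a 1-D expression gradient
        rng = np.random.default_rng(1)
        n = 80
        base = np.linspace(0, 4, n)[:, None] * np.ones((1, 20))
        X = base + rng.normal(0, 0.01, size=(n, 20))
        t = np.repeat(np.arange(5, 15), 8).astype(float)
        pt = compute_pseudotime(X, t, n_pcs=10, k=8, seed=0)
        # the root (pseudotime 0) is one of the minimum-time cells
        assert np.min(pt) == 0.0 and np.argmin(pt) < 8
        rho = concordance(np.arange(n, dtype=float), pt)
        assert rho > 0.99

    def test_deterministic_given_seed(self, default_fixture, default_norm):
        _, expr, _, truth = default_fixture
        t = truth.cells["true_time_hpf"].to_numpy()
        pt1 = compute_pseudotime(default_norm, t, seed=3)
        pt2 = compute_pseudotime(default_norm, t, seed=3)
        np.testing.assert_array_equal(pt1, pt2)

    def test_tracks_true_time_on_default_fixture(self, default_fixture, default_norm):
        cfg, expr, _, truth = default_fixture
        t = truth.cells["true_time_hpf"].to_numpy()
        pt = compute_pseudotime(default_norm, t, seed=0)
        assert concordance(t, pt) >= 0.8

    def test_requires_a_rooted_cell(self):
        with pytest.raises(ValueError):
            compute_pseudotime(np.zeros((10, 3)), np.full(10, np.nan))


class TestSegmentStates:
    def test_single_state(self):
        assert set(segment_states(np.random.default_rng(2).normal(size=(7, 3)),
                                  np.linspace(0, 1, 7), 1)) == {0}

    def test_two_separated_blobs_exact_recovery(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.05, (40, 5)), rng.normal(5, 0.05, (40, 5))])
        pt = np.concatenate([np.linspace(0, 0.4, 40), np.linspace(0.6, 1, 40)])
        states = segment_states(X, pt, 2)
        truth = np.repeat([0, 1], 40)
        assert adjusted_rand_score(truth, states) == 1.0
        assert states[0] == 0 and states[-1] == 1  # renumbered by pseudotime

    def test_state_medians_increase_with_pseudotime(self, default_fixture,
                                                    default_norm):
        _, expr, _, truth = default_fixture
        t = truth.cells["true_time_hpf"].to_numpy()
        pt = compute_pseudotime(default_norm, t, seed=0)
        emb = pca_embedding(default_norm, 35, seed=0)
        g = build_neighbor_graph(emb, k=18, exclude_self=True)
        sm = smooth_expression(default_norm, g.indices)
        states = segment_states(sm, pt, 5)
        medians = [np.nanmedian(pt[states == s]) for s in range(5)]
        assert all(a <= b for a, b in zip(medians, medians[1:]))

    def test_invariant_to_cell_permutation(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(i, 0.05, (25, 4)) for i in range(3)])
        pt = np.linspace(0, 1, 75)
        base = segment_states(X, pt, 3)
        perm = rng.permutation(75)
        again = segment_states(X[perm], pt[perm], 3)
        assert adjusted_rand_score(base[perm], again) == 1.0
        np.testing.assert_array_equal(base[perm], again)

    def test_too_many_states_rejected(self):
        with pytest.raises(ValueError):
            segment_states(np.zeros((3, 2)), np.zeros(3), 4)


class TestClusterGenes:
    def test_sparse_gene_filtered_out(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(5, size=(30, 10))
        X[:, 3] = 0
        X[[0, 1], 3] = 1  # expressed in exactly 2 cells < min_cells=3
        genes = [f"g{i}" for i in range(10)]
        out = cluster_genes(X, genes, min_cells=3, seed=0)
        assert "g3" not in out.index

    def test_duplicated_gene_shares_cluster(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 1, 60)
        X = np.column_stack([
            np.sin(np.pi * t) * 10, np.sin(np.pi * t) * 10,  # duplicated profile
            np.cos(np.pi * t) * 10 + 10,
        ])
        X = rng.poisson(np.maximum(X, 0.1))
        out = cluster_genes(X, ["a", "a_copy", "b"], min_cells=1, k=2, seed=0)
        assert out["a"] == out["a_copy"]

    def test_anti_correlated_programs_split(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 1, 100)
        up = np.outer(t, np.ones(10)) * 20
        down = np.outer(1 - t, np.ones(10)) * 20
        X = rng.poisson(np.hstack([up, down]) + 0.1)
        genes = [f"u{i}" for i in range(10)] + [f"d{i}" for i in range(10)]
        out = cluster_genes(X, genes, min_cells=1, k=5, seed=0)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, out.loc[genes]) == 1.0

    def test_recovers_planted_clusters(self, default_fixture):
        cfg, expr, _, truth = default_fixture
        out = cluster_genes(np.asarray(expr.X), list(expr.var_names), seed=0)
        tg = truth.genes.loc[out.index, "true_cluster"]
        assert adjusted_rand_score(tg, out) >= 0.9

    def test_all_genes_filtered_raises(self):
        with pytest.raises(ValueError):
            cluster_genes(np.zeros((10, 5), dtype=int), list("abcde"), min_cells=3)


@pytest.fixture(scope="module")
def labeled(default_fixture, default_norm):
    cfg, expr, _, truth = default_fixture
    assign = cluster_genes(np.asarray(expr.X), list(expr.var_names), seed=0)
    table = cluster_profiles(default_norm, list(expr.var_names), assign,
                             truth.cells["true_time_hpf"].to_numpy(),
                             truth.cells["true_lineage"].to_numpy(),
                             cfg.bifurcation_time)
    return cfg, truth, label_maturity(table, cfg.bifurcation_time)


class TestMaturityLabels:

    def test_mature_program_recovered(self, labeled):
        cfg, truth, table = labeled
        found = table.genes_with_maturity("mature")
        want = set(truth.genes.index[truth.genes["true_maturity"] == "mature"])
        jac = len(found & want) / len(found | want)
        assert jac >= 0.7

    def test_immature_is_earliest_founder_program(self, labeled):
        cfg, truth, table = labeled
        found = table.genes_with_maturity("immature")
        want = set(truth.genes.index[truth.genes["true_maturity"] == "immature"])
        assert len(found & want) / len(found | want) >= 0.7

    def test_terminal_clusters_are_branch_restricted(self, labeled):
        cfg, truth, table = labeled
        for c in table.maturity[table.maturity == "terminal"].index:
            vals = table.branch_profiles.loc[c].sort_values(ascending=False)
            assert vals.iloc[0] > 0 >= vals.iloc[1]

    def test_constant_profile_cluster_unlabeled(self):
        prof = pd.DataFrame([[0.0] * 5, [1.0, 0.5, 0.0, -0.5, -1.0]],
                            index=[0, 1], columns=[5.0, 6, 7, 8, 9])
        from chronotrace.trajectory import GeneClusterTable

        table = GeneClusterTable(
            assignments=pd.Series({"gA": 0, "gB": 1}),
            profiles=prof, peak_time_hpf=prof.idxmax(axis=1).astype(float))
        out = label_maturity(table, bifurcation_time=8.0)
        assert out.maturity[0] == "unlabeled"

    def test_no_time_bins_rejected(self):
        from chronotrace.trajectory import GeneClusterTable

        empty = GeneClusterTable(assignments=pd.Series(dtype=int),
                                 profiles=pd.DataFrame(index=[0]),
                                 peak_time_hpf=pd.Series(dtype=float))
        with pytest.raises(ValueError):
            label_maturity(empty, 8.0)


class TestFindMarkers:
    def test_identical_groups_yield_no_markers(self):
        rng = np.random.default_rng(8)
        X = rng.normal(1, 0.1, size=(80, 12))
        groups = np.repeat(["a", "b"], 40)
        out = find_markers(X, [f"g{i}" for i in range(12)], groups)
        assert len(out) == 0

    def test_planted_fourfold_gene_detected(self):
        rng = np.random.default_rng(9)
        n = 200
        base = rng.poisson(10, size=(2 * n, 20))
        base[:n, 0] *= 4  # 4-fold higher in group a
        norm = normalize_log1p_cp10k(base)
        groups = np.repeat(["a", "b"], n)
        out = find_markers(norm, [f"g{i}" for i in range(20)], groups)
        hits = out[(out["gene"] == "g0") & (out["group"] == "a")]
        assert len(hits) == 1
        assert hits.iloc[0]["avg_log2fc"] >= 0.25
        assert hits.iloc[0]["p_adj"] < 0.1

    def test_small_fold_change_excluded_regardless_of_p(self):
        rng = np.random.default_rng(10)
        n = 500
        X = np.zeros((2 * n, 2))
        X[:n, 0] = rng.normal(10.0, 0.01, n)       # tiny but ultra-consistent shift
        X[n:, 0] = rng.normal(9.0, 0.01, n)        # log2(10/9) ~ 0.152 < 0.25
        X[:, 1] = rng.normal(5.0, 1.0, 2 * n)
        groups = np.repeat(["hi", "lo"], n)
        out = find_markers(np.log1p(X), ["shift", "flat"], groups)
        assert "shift" not in set(out["gene"])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            find_markers(np.zeros((4, 2)), ["a", "b"], np.array(["g"] * 4))


class TestVelocitySpeed:
    def test_constant_expression_zero_speed(self):
        pt = np.linspace(0, 1, 30)
        X = np.ones((30, 5))
        np.testing.assert_allclose(velocity_speed(X, pt), 0.0)

    def test_linear_gene_slope_two(self):
        pt = np.linspace(0, 1, 41)
        X = np.column_stack([2 * pt, np.ones(41), np.full(41, 3.0)])
        speed = velocity_speed(X, pt, half_window=5)
        np.testing.assert_allclose(speed, 2.0, rtol=1e-12)

    def test_appending_constant_genes_leaves_speed_unchanged(self):
        rng = np.random.default_rng(11)
        pt = np.sort(rng.random(50))
        X = rng.normal(size=(50, 6))
        base = velocity_speed(X, pt)
        padded = np.hstack([X, np.ones((50, 3))])
        np.testing.assert_allclose(velocity_speed(padded, pt), base)

    def test_constant_pseudotime_rejected(self):
        with pytest.raises(ValueError):
            velocity_speed(np.zeros((20, 2)), np.ones(20))


class TestIntersectMaturitySets:
    def test_disjoint_sets_zero_overlap(self):
        out = intersect_maturity_sets({"a": {1, 2}, "b": {3, 4}})
        assert out.set_index("label").loc["a & b", "size"] == 0

    def test_subset_relation(self):
        out = intersect_maturity_sets({"A": {1, 2}, "B": {1, 2, 3}})
        assert out.set_index("label").loc["A & B", "size"] == 2

    def test_three_way_overlap_counts_and_shared_fraction(self):
        # two lineages sharing 97 of 112/113 members: the shared fraction
        # of the smaller set is 97/112 = 86.6%
        a = set(range(112))
        b = set(range(15, 15 + 113))   # overlap with a: 97
        out = intersect_maturity_sets({"LA": a, "LB": b}).set_index("label")
        assert out.loc["LA & LB", "size"] == 97
        assert round(100 * 97 / 112, 1) == 86.6
        three = intersect_maturity_sets({"x": {1, 2, 3}, "y": {2, 3}, "z": {3}})
        assert three.set_index("label").loc["x & y & z", "size"] == 1

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            intersect_maturity_sets({"only": {1}})
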