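import numpy as np
import pytest
import scipy.stats

from exoatlas.embed_cluster import ClusterLabels
from exoatlas.trajectory import (
    BranchFeatureTable,
    TrajectoryGraph,
    assign_pseudotime,
    branch_cell_mask,
    branch_features,
    build_mst,
    rank_tip_genes,
    subset_lineage,
)
from oracles import min_spanning_weight_oracle, project_oracle

import pandas as pd


class TestSubsetLineage:
    def test_counts_cells_of_selected_clusters(self, rng):
        x = rng.normal(size=(30, 4))
        labels = ClusterLabels(np.repeat([0, 1, 2], 10))
        sub, idx = subset_lineage(x, labels, [0, 2])
        assert sub.shape == (20, 4)
        assert set(labels.labels[idx]) == {0, 2}

    def test_select_all_is_identity(self, rng):
        x = rng.normal(size=(12, 3))
        labels = ClusterLabels(np.repeat([0, 1], 6))
        sub, idx = subset_lineage(x, labels, [0, 1])
        assert np.array_equal(sub, x)

    def test_empty_selection_rejected(self, rng):
        labels = ClusterLabels(np.zeros(5, int))
        with pytest.raises(ValueError, match="empty"):
            subset_lineage(rng.normal(size=(5, 2)), labels, [])

    def test_unknown_cluster_rejected(self, rng):
        labels = ClusterLabels(np.zeros(5, int))
        with pytest.raises(ValueError, match="unknown cluster"):
            subset_lineage(rng.normal(size=(5, 2)), labels, [3])


class TestBuildMST:
    def test_collinear_path(self):
        g = build_mst({0: [0.0, 0.0], 1: [1.0, 0.0], 2: [3.0, 0.0]})
        assert sorted((u, v, round(w, 9)) for u, v, w in g.edges) == [
            (0, 1, 1.0),
            (1, 2, 2.0),
        ]

    def test_two_milestones_single_edge(self):
        g = build_mst({0: [0.0, 0.0], 1: [0.0, 2.5]})
        assert g.edges == [(0, 1, 2.5)]

    def test_duplicate_centroids_rejected(self):
        with pytest.raises(ValueError, match="duplicate centroids"):
            build_mst({0: [1.0, 1.0], 1: [1.0, 1.0]})

    def test_single_milestone_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_mst({0: [0.0]})

    @pytest.mark.parametrize("seed", range(10))
    def test_optimal_vs_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        pts = rng.normal(size=(n, 3))
        g = build_mst({i: pts[i] for i in range(n)})
        total = sum(w for _, _, w in g.edges)
        dist = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        assert np.isclose(total, min_spanning_weight_oracle(dist))

    def test_spanning_tree_invariants_enforced(self):
        with pytest.raises(ValueError, match="edge count"):
            TrajectoryGraph(
                centroids={0: np.zeros(2), 1: np.ones(2), 2: 2 * np.ones(2)},
                edges=[(0, 1, 1.0)],
            )
        with pytest.raises(ValueError, match="connect"):
            TrajectoryGraph(
                centroids={i: np.array([float(i), 0.0]) for i in range(4)},
                edges=[(0, 1, 1.0), (0, 1, 1.0), (2, 3, 1.0)],
            )


def path_graph():
    return build_mst({0: [0.0, 0.0], 1: [1.0, 0.0], 2: [3.0, 0.0]})


class TestAssignPseudotime:
    def test_cell_at_root_centroid(self):
        g = path_graph()
        a = assign_pseudotime(g, 0, np.array([[0.0, 0.0]]))
        assert a.pseudotime[0] == 0.0

    def test_forced_geometry_on_path(self):
        g = path_graph()
        a = assign_pseudotime(g, 0, np.array([[2.0, 0.0], [0.5, 0.1]]))
        assert np.isclose(a.pseudotime[0], 2.0)
        assert a.edge[0] == (1, 2)
        assert np.isclose(a.pseudotime[1], 0.5)

    def test_root_must_be_milestone(self):
        with pytest.raises(ValueError, match="root"):
            assign_pseudotime(path_graph(), 9, np.zeros((1, 2)))

    def test_milestones_map_to_their_geodesic_distance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 4)) * 3
        g = build_mst({i: pts[i] for i in range(6)})
        a = assign_pseudotime(g, 0, pts)
        dist = g.distances_from(0)
        for i in range(6):
            assert np.isclose(a.pseudotime[i], dist[i])

    def test_monotone_along_root_to_leaf_paths(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 3)) * 2
        g = build_mst({i: pts[i] for i in range(7)})
        a = assign_pseudotime(g, 0, pts)
        dist = g.distances_from(0)
        for leaf in g.leaves():
            path = g.root_path_edges(leaf)
            ordered = sorted(
                {m for e in path for m in e}, key=lambda m: dist[m]
            )
            pts_on_path = [a.pseudotime[m] for m in ordered]
            assert all(x <= y + 1e-12 for x, y in zip(pts_on_path, pts_on_path[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        pts = rng.normal(size=(n, 3)) * 2
        cells = rng.normal(size=(25, 3)) * 2.5
        g = build_mst({i: pts[i] for i in range(n)})
        a = assign_pseudotime(g, 0, cells)
        expected = project_oracle(
            {i: pts[i] for i in range(n)}, g.edges, 0, cells
        )
        for i, (pt, edge) in enumerate(expected):
            assert a.edge[i] == edge
            assert np.isclose(a.pseudotime[i], pt, atol=1e-10)


def line_lineage(rng, n=300, n_genes=30):
    """Cells along a single segment with planted feature patterns."""
    t = np.sort(rng.uniform(0, 10, n))
    cells = np.column_stack([t, rng.normal(scale=0.05, size=n)])
    g = build_mst({0: [0.0, 0.0], 1: [5.0, 0.0], 2: [10.0, 0.0]})
    a = assign_pseudotime(g, 0, cells)
    x = rng.poisson(1.0, size=(n, n_genes)).astype(float)
    x[:, 0] = 0.0
    x[t >= 8.0, 0] = rng.uniform(2, 3, (t >= 8.0).sum())  # tip-restricted
    x[:, 1] = rng.uniform(0.5, 1.5, n)  # uniform
    x[:, 2] = 0.0  # absent
    return x, a, g, t


class TestBranchFeatures:
    def test_tip_restricted_gene_scores_high(self, rng):
        x, a, g, t = line_lineage(rng)
        feats = branch_features(x, a, g)
        leaf = feats.branches[0]
        assert feats.tip_restriction.loc["0", leaf] > 10
        assert feats.correlation.loc["0", leaf] > 0

    def test_uniform_gene_uncorrelated(self, rng):
        x, a, g, t = line_lineage(rng)
        feats = branch_features(x, a, g)
        leaf = feats.branches[0]
        assert abs(feats.correlation.loc["1", leaf]) < 0.2

    def test_absent_gene_zero_tip_restriction(self, rng):
        x, a, g, t = line_lineage(rng)
        feats = branch_features(x, a, g)
        leaf = feats.branches[0]
        assert feats.tip_restriction.loc["2", leaf] == 0.0

    def test_small_branch_skipped_with_warning(self, rng):
        x, a, g, t = line_lineage(rng, n=5)
        with pytest.warns(UserWarning, match="fewer than"):
            feats = branch_features(x, a, g, min_branch_cells=10)
        assert feats.tip_restriction.empty

    def test_branch_mask_covers_root_path(self, rng):
        x, a, g, t = line_lineage(rng)
        leaf = g.leaves()[0]
        mask = branch_cell_mask(a, g, leaf)
        assert mask.all()  # single path: every cell lies on it


class TestRankTipGenes:
    def test_ordering_and_k(self, rng):
        x, a, g, t = line_lineage(rng)
        feats = branch_features(x, a, g)
        leaf = feats.branches[0]
        ranked = rank_tip_genes(feats, leaf)
        assert ranked[0] == "0"
        assert rank_tip_genes(feats, leaf, k=5) == ranked[:5]
        assert rank_tip_genes(feats, leaf, k=10**6) == ranked

    def test_empty_table(self):
        feats = BranchFeatureTable(
            correlation=pd.DataFrame(), tip_restriction=pd.DataFrame()
        )
        assert rank_tip_genes(feats, "anything") == []

    def test_unknown_branch_rejected(self, rng):
        x, a, g, t = line_lineage(rng)
        feats = branch_features(x, a, g)
        with pytest.raises(ValueError, match="unknown branch"):
            rank_tip_genes(feats, 999)


class TestEndToEndRecovery:
    def test_pseudotime_and_tip_genes_recovered(self, default_atlas):
        """Planted branch order and tip genes are recovered on seed 7."""
        from exoatlas.evaluation import run_atlas_recovery

        r = run_atlas_recovery(7)
        assert r.branch_spearman  # all three branches measured
        for b, rho in r.branch_spearman.items():
            assert rho > 0.7, (b, rho)
        assert r.tip_recall is not None and r.tip_recall >= 0.8
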