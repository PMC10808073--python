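"""MST pseudotime over cluster-centroid milestones.

Milestones are cluster centroids in a low-dimensional embedding of the
lineage subset.  They are joined by a Euclidean minimum spanning tree,
rooted in the milestone carrying the meristem annotation.  Each cell is
orthogonally projected onto its nearest tree edge; its pseudotime is
the geodesic tree distance from the root to the projection, and its
branch is the leaf milestone downstream of its edge.

Trajectory-variable genes are scored transparently: per-branch Spearman
correlation of expression with pseudotime, per-milestone marker
statistics, and a tip-restriction ratio (mean expression in the
terminal quantile of a branch over mean expression in the rest of the
lineage) used to nominate genes confined to a branch terminus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .embed_cluster import ClusterLabels, ClusterMarkers, find_markers


@dataclass
class TrajectoryGraph:
    """Milestones with centroid coordinates joined by a spanning tree."""

    centroids: dict  # milestone id -> coordinate array
    edges: list  # (u, v, length) with u < v
    root: object | None = None

    def __post_init__(self) -> None:
        ids = set(self.centroids)
        if len(self.edges) != len(ids) - 1:
            raise ValueError("edge count must equal milestone count - 1")
        adj = {i: [] for i in ids}
        for u, v, w in self.edges:
            if w <= 0:
                raise ValueError("edge lengths must be positive")
            adj[u].append((v, w))
            adj[v].append((u, w))
        # connectivity check (spanning)
        seen = set()
        stack = [next(iter(ids))] if ids else []
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(v for v, _ in adj[u] if v not in seen)
        if seen != ids:
            raise ValueError("edges do not connect all milestones")
        self._adj = adj

    @property
    def milestones(self) -> list:
        return sorted(self.centroids)

    def distances_from(self, source) -> dict:
        """Geodesic tree distance from ``source`` to every milestone."""
        if source not in self.centroids:
            raise ValueError(f"unknown milestone {source!r}")
        dist = {source: 0.0}
        stack = [source]
        while stack:
            u = stack.pop()
            for v, w in self._adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    def leaves(self) -> list:
        """Degree-1 milestones other than the root."""
        deg1 = [i for i in self.milestones if len(self._adj[i]) == 1]
        return [i for i in deg1 if i != self.root] or deg1

    def root_path_edges(self, leaf) -> set:
        """Edges (u, v) on the path from the root to ``leaf``."""
        if self.root is None:
            raise ValueError("graph is not rooted")
        parent = {self.root: None}
        stack = [self.root]
        while stack:
            u = stack.pop()
            for v, _ in self._adj[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        path = set()
        node = leaf
        while parent[node] is not None:
            u, v = parent[node], node
            path.add((min(u, v), max(u, v)))
            node = parent[node]
        return path


@dataclass
class PseudotimeAssignment:
    """Per-cell projection onto the trajectory tree."""

    edge: list  # (u, v) per cell, u < v
    position: np.ndarray  # arc length from the edge's root-ward endpoint
    pseudotime: np.ndarray
    branch: np.ndarray  # leaf milestone id per cell

    def __post_init__(self) -> None:
        if np.any(self.pseudotime < 0):
            raise ValueError("negative pseudotime")


@dataclass
class BranchFeatureTable:
    """Per-gene trajectory scores.

    ``correlation``: genes x branches Spearman correlation with
    pseudotime within the branch.  ``tip_restriction``: genes x
    branches ratio of mean expression in the branch's terminal quantile
    to mean expression in the remaining lineage cells.
    """

    correlation: pd.DataFrame
    tip_restriction: pd.DataFrame
    milestone_markers: ClusterMarkers | None = None

    @property
    def branches(self) -> list:
        return list(self.tip_restriction.columns)


def subset_lineage(matrix, labels: ClusterLabels, selected_clusters):
    """Select the cells of the given clusters.

    Returns (subset matrix, index array).  The caller re-embeds and
    re-clusters the subset (see :func:`infer_trajectory`).
    """
    selected = list(selected_clusters)
    if not selected:
        raise ValueError("empty cluster selection")
    known = set(np.unique(labels.labels).tolist())
    unknown = [c for c in selected if c not in known]
    if unknown:
        raise ValueError(f"unknown cluster id(s): {unknown}")
    mask = np.isin(labels.labels, selected)
    idx = np.where(mask)[0]
    if hasattr(matrix, "subset"):
        return matrix.subset(cell_idx=idx), idx
    sub = matrix[idx] if sp.issparse(matrix) else np.asarray(matrix)[idx]
    return sub, idx


def cluster_centroids(coords: np.ndarray, labels: ClusterLabels) -> dict:
    return {
        int(c): coords[labels.labels == c].mean(axis=0)
        for c in np.unique(labels.labels)
    }


def build_mst(centroids: dict) -> TrajectoryGraph:
    """Euclidean minimum spanning tree over milestone centroids.

    Kruskal's algorithm with ties broken by the (smaller id, larger id)
    edge ordering, so the tree is deterministic.  Duplicate centroids
    are rejected (zero-length edges would break the tree metric).
    """
    ids = sorted(centroids)
    if len(ids) < 2:
        raise ValueError("need at least 2 milestones")
    pts = {i: np.asarray(centroids[i], dtype=float) for i in ids}
    cand = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            u, v = ids[a], ids[b]
            d = float(np.linalg.norm(pts[u] - pts[v]))
            if d == 0.0:
                raise ValueError(f"duplicate centroids for milestones {u} and {v}")
            cand.append((d, u, v))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))

    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges = []
    for d, u, v in cand:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            edges.append((u, v, d))
        if len(edges) == len(ids) - 1:
            break
    return TrajectoryGraph(centroids=pts, edges=edges)


def assign_pseudotime(
    g: TrajectoryGraph, root, cell_coords: np.ndarray
) -> PseudotimeAssignment:
    """Project cells onto the tree and measure geodesic pseudotime.

    Each cell is projected orthogonally onto every edge and assigned to
    the nearest one; ties go to the first edge in sorted order.
    Projections are clamped to the segment at internal milestones but
    may extrapolate past a terminal (degree-1) milestone, so cells
    beyond a branch tip keep their ordering instead of collapsing onto
    the tip centroid.  Pseudotime is the tree distance from the root to
    the projected point (never below zero).
    """
    if root not in g.centroids:
        raise ValueError(f"root {root!r} is not a milestone")
    g.root = root
    dist = g.distances_from(root)
    coords = np.asarray(cell_coords, dtype=float)
    n = len(coords)

    degree = {i: len(g._adj[i]) for i in g.centroids}
    edge_list = sorted((min(u, v), max(u, v), w) for u, v, w in g.edges)
    best_d2 = np.full(n, np.inf)
    best_edge = np.full(n, -1)
    best_t = np.zeros(n)
    for k, (u, v, L) in enumerate(edge_list):
        a, b = g.centroids[u], g.centroids[v]
        ab = b - a
        lo = -np.inf if degree[u] == 1 else 0.0
        hi = np.inf if degree[v] == 1 else 1.0
        t = np.clip((coords - a) @ ab / (L * L), lo, hi)
        proj = a + t[:, None] * ab
        d2 = ((coords - proj) ** 2).sum(axis=1)
        better = d2 < best_d2 - 1e-15
        best_d2[better] = d2[better]
        best_edge[better] = k
        best_t[better] = t[better]

    leaves = g.leaves()
    leaf_paths = {l: g.root_path_edges(l) for l in leaves}

    edges_out, pt, pos, branch = [], np.zeros(n), np.zeros(n), np.empty(n, dtype=object)
    for i in range(n):
        u, v, L = edge_list[best_edge[i]]
        t = best_t[i]
        # orient from the root-ward endpoint
        if dist[u] <= dist[v]:
            par, offset = u, t * L
        else:
            par, offset = v, (1 - t) * L
        edges_out.append((u, v))
        pos[i] = offset
        pt[i] = max(0.0, dist[par] + offset)
        child = v if par == u else u
        cands = [l for l in leaves if (u, v) in leaf_paths[l]]
        if not cands:
            # edge hangs root-ward of every leaf path (root is a leaf-side
            # stub); fall back to the nearest leaf from the child endpoint
            cands = leaves
        branch[i] = min(cands, key=lambda l: (abs(dist[l] - dist[child]), l))
    return PseudotimeAssignment(edge=edges_out, position=pos, pseudotime=pt, branch=branch)


def branch_cell_mask(a: PseudotimeAssignment, g: TrajectoryGraph, leaf) -> np.ndarray:
    """Cells whose edge lies on the root-to-``leaf`` path."""
    path = g.root_path_edges(leaf)
    return np.array([e in path for e in a.edge])


def branch_features(
    x,
    a: PseudotimeAssignment,
    g: TrajectoryGraph,
    genes=None,
    q: float = 0.2,
    eps: float = 1e-6,
    min_branch_cells: int = 10,
    milestone_labels: ClusterLabels | None = None,
) -> BranchFeatureTable:
    """Score genes along branches of the trajectory.

    For every branch (root-to-leaf path): the Spearman correlation of
    each gene with pseudotime over the branch's cells, and the
    tip-restriction ratio of mean expression in the terminal ``q``
    quantile of the branch to mean expression in all other lineage
    cells (plus ``eps``).  If ``milestone_labels`` is given, milestone
    marker statistics are computed with :func:`find_markers`.
    """
    dense = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    n, n_genes = dense.shape
    if genes is None:
        genes = np.array([str(i) for i in range(n_genes)], dtype=object)
    genes = np.asarray(genes, dtype=object)

    corr, tip = {}, {}
    for leaf in g.leaves():
        mask = branch_cell_mask(a, g, leaf)
        if mask.sum() < min_branch_cells:
            warnings.warn(f"branch {leaf} has fewer than {min_branch_cells} cells; skipped")
            continue
        xb = dense[mask]
        ptb = a.pseudotime[mask]
        # vectorized Spearman: Pearson correlation of ranks
        rx = scipy.stats.rankdata(xb, axis=0)
        rp = scipy.stats.rankdata(ptb)
        rx = rx - rx.mean(axis=0)
        rp = rp - rp.mean()
        denom = np.sqrt((rx**2).sum(axis=0) * (rp**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, rx.T @ rp / np.maximum(denom, 1e-300), 0.0)
        corr[leaf] = rho

        cut = np.quantile(ptb, 1 - q)
        tip_mask = np.zeros(n, dtype=bool)
        tip_mask[np.where(mask)[0][ptb >= cut]] = True
        mean_tip = dense[tip_mask].mean(axis=0)
        mean_rest = dense[~tip_mask].mean(axis=0)
        tip[leaf] = mean_tip / (mean_rest + eps)

    markers = None
    if milestone_labels is not None and milestone_labels.n_clusters >= 2:
        markers = find_markers(dense, milestone_labels, genes=genes)

    return BranchFeatureTable(
        correlation=pd.DataFrame(corr, index=genes),
        tip_restriction=pd.DataFrame(tip, index=genes),
        milestone_markers=markers,
    )


def infer_trajectory(
    x_subset,
    root_cell_mask: np.ndarray,
    embed_dim: int = 10,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
    embedding: str = "pca",
):
    """Re-embed and re-cluster a lineage subset, build the rooted MST.

    The subset is embedded (PCA by default, ``embedding="umap"`` for a
    2-D UMAP of the leading PCs), re-clustered into milestones, and the
    milestone centroids joined by an MST rooted at the milestone with
    the largest share of ``root_cell_mask`` cells (e.g. cells annotated
    as meristem).

    Returns (TrajectoryGraph, PseudotimeAssignment, milestone ClusterLabels).
    """
    from .embed_cluster import cluster_cells, pca_embed, umap_embed

    emb = pca_embed(x_subset, n_pcs=max(embed_dim, 2))
    labels = cluster_cells(
        emb, n_use=embed_dim, k_neighbors=k_neighbors, resolution=resolution, seed=seed
    )
    if embedding == "umap":
        coords = umap_embed(emb, n_use=emb.n_components, seed=seed).coordinates
    else:
        coords = emb.coordinates[:, :embed_dim]

    root_cell_mask = np.asarray(root_cell_mask, dtype=bool)
    if not root_cell_mask.any():
        raise ValueError("no root cells in the lineage subset")
    shares = {
        int(c): root_cell_mask[labels.labels == c].mean()
        for c in np.unique(labels.labels)
    }
    root = max(sorted(shares), key=lambda c: shares[c])

    graph = build_mst(cluster_centroids(coords, labels))
    assignment = assign_pseudotime(graph, root, coords)
    return graph, assignment, labels


def rank_tip_genes(t: BranchFeatureTable, branch, k: int | None = None) -> list:
    """Genes ranked by tip restriction (descending), ties by correlation."""
    if branch not in t.tip_restriction.columns:
        if t.tip_restriction.empty:
            return []
        raise ValueError(f"unknown branch {branch!r}")
    df = pd.DataFrame(
        {
            "tip": t.tip_restriction[branch],
            "corr": t.correlation[branch]
            if branch in t.correlation
            else 0.0,
        }
    )
    df = df.sort_values(["tip", "corr"], ascending=False, kind="mergesort")
    ranked = list(df.index)
    return ranked if k is None else ranked[:k]
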