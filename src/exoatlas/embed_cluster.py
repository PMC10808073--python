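"""Normalization, PCA embedding, graph clustering, marker detection.

The conventions follow common droplet scRNA-seq practice: per-cell
library-size normalization to a fixed scale with a natural log1p
transform, PCA on the centered normalized matrix, Leiden community
detection on a k-nearest-neighbour graph built in PC space, and
positive-only Wilcoxon rank-sum marker detection gated on expressed
fraction (min_pct) and log fold-change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core_io import CountMatrix

LFC_PSEUDOCOUNT = 1e-9


@dataclass
class Embedding:
    """A linear or nonlinear cell embedding (cells x d)."""

    coordinates: np.ndarray
    kind: str = "pca"
    variances: np.ndarray | None = None  # per-component, PCA only
    components: np.ndarray | None = None  # d x genes loadings, PCA only
    mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite embedding coordinates")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ClusterLabels:
    """Per-cell integer cluster assignment with contiguous ids from 0."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        ids = np.unique(self.labels)
        if len(ids) and not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def cluster_sizes(self) -> dict:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class ClusterMarkers:
    """Ranked positive marker records per cluster.

    ``table`` holds one row per (cluster, gene) that passed the pct and
    fold-change gates, with Wilcoxon p-values and a Bonferroni
    adjustment over the genes tested for that cluster.  ``sets`` maps a
    cluster id to its significant marker set S_i.
    """

    table: pd.DataFrame
    alpha: float = 0.05

    @property
    def sets(self) -> dict:
        sig = self.table[self.table["p_adj"] < self.alpha]
        out: dict = {int(c): set() for c in self.table["cluster"].unique()}
        for c, sub in sig.groupby("cluster"):
            out[int(c)] = set(sub["gene"])
        return out


def lognormalize(m: CountMatrix, scale: float = 1e4) -> sp.csr_matrix:
    """Library-size normalize and log-transform: x' = ln(1 + c*scale/total).

    Zeros are preserved; a zero-total cell is an error (it should have
    been removed by QC).
    """
    totals = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValueError("zero-total cell encountered; run QC first")
    x = sp.csr_matrix(m.counts, dtype=float, copy=True)
    factor = scale / totals
    x.data *= np.repeat(factor, np.diff(x.indptr))
    x.data = np.log1p(x.data)
    return x


def pca_embed(x, n_pcs: int = 50) -> Embedding:
    """Centered PCA with a deterministic sign convention.

    Each component is flipped so its largest-magnitude loading is
    positive.  If ``n_pcs`` exceeds the data rank the component count
    is reduced with a warning.
    """
    dense = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    max_pcs = min(dense.shape[0] - 1, dense.shape[1])
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs reduced from {n_pcs} to rank bound {max_pcs}")
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(dense)
    comps = pca.components_
    flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    coords = coords * flip
    comps = comps * flip[:, None]
    return Embedding(
        coordinates=coords,
        kind="pca",
        variances=pca.explained_variance_.copy(),
        components=comps,
        mean=pca.mean_.copy(),
    )


def umap_embed(e: Embedding, n_use: int = 35, n_components: int = 2, seed: int = 0):
    """2-D UMAP of the leading principal components (optional plumbing)."""
    import umap  # deferred; optional dependency

    reducer = umap.UMAP(n_components=n_components, random_state=seed)
    coords = reducer.fit_transform(e.coordinates[:, :n_use])
    return Embedding(coordinates=np.asarray(coords, dtype=float), kind="umap")


def knn_graph(coords: np.ndarray, k_neighbors: int) -> igraph.Graph:
    """Undirected kNN graph (union of directed neighbourhoods)."""
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return igraph.Graph(n=len(coords), edges=sorted(edges))


def cluster_cells(
    e: Embedding,
    n_use: int = 35,
    k_neighbors: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
) -> ClusterLabels:
    """Leiden community detection on a kNN graph in PC space.

    Clusters are relabelled by decreasing size (ties by first cell
    index) so that labels are stable up to the partition itself.
    """
    coords = e.coordinates[:, : min(n_use, e.n_components)]
    if len(coords) <= k_neighbors:
        raise ValueError(
            f"k_neighbors={k_neighbors} requires more than that many cells"
        )
    g = knn_graph(coords, k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.array(part.membership)
    order = sorted(
        np.unique(raw),
        key=lambda c: (-int((raw == c).sum()), int(np.argmax(raw == c))),
    )
    remap = {c: i for i, c in enumerate(order)}
    return ClusterLabels(np.array([remap[c] for c in raw]))


def _log_fold_change(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """ln ratio of de-logged group means with a small pseudocount."""
    mean_in = np.expm1(x_in).mean(axis=0)
    mean_out = np.expm1(x_out).mean(axis=0)
    return np.log(mean_in + LFC_PSEUDOCOUNT) - np.log(mean_out + LFC_PSEUDOCOUNT)


def find_markers(
    x,
    labels: ClusterLabels,
    genes=None,
    min_pct: float = 0.1,
    lfc_min: float = 0.25,
    alpha: float = 0.05,
) -> ClusterMarkers:
    """Positive marker detection, each cluster versus all other cells.

    Genes are tested only if their expressed fraction reaches
    ``min_pct`` in at least one of the two groups and their log
    fold-change is positive and at least ``lfc_min``.  P-values come
    from the two-sided Wilcoxon rank-sum test (normal approximation)
    and are Bonferroni-adjusted over the genes tested for the cluster.
    """
    dense = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    lab = labels.labels
    ids = np.unique(lab)
    if len(ids) < 2:
        raise ValueError("marker detection requires >= 2 clusters")
    if genes is None:
        genes = np.array([str(i) for i in range(dense.shape[1])], dtype=object)
    genes = np.asarray(genes, dtype=object)

    rows = []
    for c in ids:
        in_mask = lab == c
        if in_mask.sum() < 2:
            warnings.warn(f"cluster {c} has fewer than 2 cells; skipped")
            continue
        x_in, x_out = dense[in_mask], dense[~in_mask]
        pct_in = (x_in > 0).mean(axis=0)
        pct_out = (x_out > 0).mean(axis=0)
        lfc = _log_fold_change(x_in, x_out)
        tested = (np.maximum(pct_in, pct_out) >= min_pct) & (lfc >= lfc_min) & (lfc > 0)
        n_tested = int(tested.sum())
        if n_tested == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = scipy.stats.mannwhitneyu(
                x_in[:, tested],
                x_out[:, tested],
                axis=0,
                alternative="two-sided",
                method="asymptotic",
            )
        p = np.atleast_1d(res.pvalue)
        p_adj = np.minimum(1.0, p * n_tested)
        for j, gi in enumerate(np.where(tested)[0]):
            rows.append(
                (
                    int(c),
                    genes[gi],
                    float(pct_in[gi]),
                    float(pct_out[gi]),
                    float(lfc[gi]),
                    float(p[j]),
                    float(p_adj[j]),
                )
            )
    table = pd.DataFrame(
        rows,
        columns=["cluster", "gene", "pct_in", "pct_out", "log_fc", "p", "p_adj"],
    )
    if len(table):
        table = table.sort_values(
            ["cluster", "p_adj", "p", "log_fc"],
            ascending=[True, True, True, False],
            kind="mergesort",
        ).reset_index(drop=True)
    return ClusterMarkers(table=table, alpha=alpha)
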