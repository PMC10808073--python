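"""Independent brute-force oracles used to cross-check the implementation.

Every function here is written from the definition of the operation it
checks, deliberately avoiding the code paths (and where possible the
library calls) used by the package itself.
"""

from __future__ import annotations

import heapq
import itertools
import math

import numpy as np
import scipy.stats

# --------------------------------------------------------------------------
# QC filter: naive dense-loop re-implementation
# --------------------------------------------------------------------------


def qc_filter_oracle(counts, organellar_mask, induced_idx, min_cells=4,
                     min_umi=500, max_organellar_frac=0.01):
    """Return (kept cell indices, kept gene indices) by plain loops."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape

    keep_gene = []
    for g in range(n_genes):
        if g in induced_idx:
            continue
        n_det = 0
        for c in range(n_cells):
            if counts[c, g] > 0:
                n_det += 1
        if n_det >= min_cells:
            keep_gene.append(g)

    keep_cell = []
    for c in range(n_cells):
        total = 0
        org = 0
        for g in range(n_genes):
            total += counts[c, g]
            if organellar_mask[g]:
                org += counts[c, g]
        if total < min_umi:
            continue
        if total > 0 and org / total > max_organellar_frac:
            continue
        keep_cell.append(c)
    return keep_cell, keep_gene


# --------------------------------------------------------------------------
# Wilcoxon rank-sum p-value: hand-written normal approximation
# --------------------------------------------------------------------------


def wilcoxon_p_oracle(x, y):
    """Two-sided rank-sum p (normal approx., tie-corrected, continuity)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    allv = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(allv)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    _, t = np.unique(allv, return_counts=True)
    tie = float((t**3 - t).sum())
    var = n1 * n2 / 12 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    return min(1.0, 2 * scipy.stats.norm.sf(z))


def find_markers_oracle(x, labels, min_pct=0.1, lfc_min=0.25, alpha=0.05,
                        pseudocount=1e-9):
    """Per-gene loop re-implementation of positive marker detection.

    Returns {cluster: {gene_index: (pct_in, pct_out, lfc, p, p_adj)}}.
    """
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    out = {}
    for c in sorted(set(labels.tolist())):
        mask = labels == c
        if mask.sum() < 2:
            continue
        tested = {}
        for g in range(x.shape[1]):
            xin, xout = x[mask, g], x[~mask, g]
            pct_in = float((xin > 0).mean())
            pct_out = float((xout > 0).mean())
            lfc = math.log(np.expm1(xin).mean() + pseudocount) - math.log(
                np.expm1(xout).mean() + pseudocount
            )
            if max(pct_in, pct_out) < min_pct or lfc < lfc_min or lfc <= 0:
                continue
            tested[g] = (pct_in, pct_out, lfc, wilcoxon_p_oracle(xin, xout))
        n_tested = len(tested)
        out[c] = {
            g: (pi, po, lfc, p, min(1.0, p * n_tested))
            for g, (pi, po, lfc, p) in tested.items()
        }
    return out


# --------------------------------------------------------------------------
# Overlap chi-squared: direct arithmetic from the definitions
# --------------------------------------------------------------------------


def chisq_oracle(counts, n_tissues, variant="standard"):
    """(statistic, p, p_corrected) from the printed definitions."""
    counts = [float(v) for v in counts]
    total = sum(counts)
    o1 = max(counts)
    e1 = total / n_tissues
    o2 = total - o1
    e2 = total * (n_tissues - 1) / n_tissues
    if variant == "standard":
        stat = (o1 - e1) ** 2 / e1 + (o2 - e2) ** 2 / e2
    else:
        stat = (o1 - e1) ** 2 / e1**2 + (o2 - e2) ** 2 / e2**2
    p = float(scipy.stats.chi2.sf(stat, 1))
    p = max(p, np.nextafter(0, 1))
    return stat, p, min(1.0, n_tissues * p)


# --------------------------------------------------------------------------
# MST: exhaustive minimum over all spanning trees via Pruefer sequences
# --------------------------------------------------------------------------


def _prufer_to_edges(seq, n):
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for v in seq:
        u = heapq.heappop(leaves)
        edges.append((u, v))
        degree[u] -= 1
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u, v = [i for i in range(n) if degree[i] == 1]
    edges.append((u, v))
    return edges


def min_spanning_weight_oracle(dist):
    """Minimum spanning-tree weight by enumerating all n^(n-2) trees."""
    dist = np.asarray(dist, float)
    n = len(dist)
    if n == 2:
        return float(dist[0, 1])
    best = math.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        w = sum(dist[u, v] for u, v in _prufer_to_edges(seq, n))
        best = min(best, w)
    return float(best)


# --------------------------------------------------------------------------
# Tree projection: dense enumeration of edges and positions
# --------------------------------------------------------------------------


def project_oracle(centroids, edges, root, cells):
    """Per-cell (pseudotime, nearest edge) by explicit enumeration.

    Mirrors the projection contract: orthogonal projection clamped at
    internal milestones, extrapolation allowed past degree-1 ones,
    geodesic distance from the root (floored at zero) via networkx.
    """
    import networkx as nx

    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    dist = nx.single_source_dijkstra_path_length(g, root)
    degree = dict(g.degree())

    results = []
    for p in np.asarray(cells, float):
        best = None
        for u, v, w in sorted((min(u, v), max(u, v), w) for u, v, w in edges):
            a = np.asarray(centroids[u], float)
            b = np.asarray(centroids[v], float)
            t = float(np.dot(p - a, b - a) / w**2)
            lo = -math.inf if degree[u] == 1 else 0.0
            hi = math.inf if degree[v] == 1 else 1.0
            t = min(max(t, lo), hi)
            proj = a + t * (b - a)
            d2 = float(((p - proj) ** 2).sum())
            if best is None or d2 < best[0] - 1e-15:
                if dist[u] <= dist[v]:
                    pt = dist[u] + t * w
                else:
                    pt = dist[v] + (1 - t) * w
                best = (d2, (u, v), max(0.0, pt))
        results.append((best[2], best[1]))
    return results


# --------------------------------------------------------------------------
# Fisher exact: two-sided hypergeometric point-probability sum
# --------------------------------------------------------------------------


def fisher_two_sided_oracle(a, b, c, d):
    """Sum of hypergeometric point probabilities <= P(observed table)."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = scipy.stats.hypergeom(n, row1, col1)
    k_lo = max(0, col1 - (n - row1))
    k_hi = min(row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(k_lo, k_hi + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, float(total))
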