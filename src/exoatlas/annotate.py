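"""Cluster annotation by marker-set overlap with a chi-squared test.

For each unsupervised cluster j, the overlap T_ij between every
reference tissue marker set M_i and the cluster's detected marker set
S_j is counted.  The tissue with the greatest overlap (O1) is tested
against a uniform expectation E1 = total/N with a two-cell
goodness-of-fit chi-squared statistic (df = 1), Bonferroni-corrected
over the N tissues in play.  If the corrected p-value is significant,
the tissue is recorded, its row is removed and the procedure repeats
for the next-highest overlap (up to ``max_rank`` labels per cluster);
the first recorded tissue is the cluster's primary annotation.

Two statistic variants are provided.  ``standard`` is the Pearson form
sum((O-E)^2 / E); ``as_printed`` divides by E^2 instead, reproducing a
non-standard published display of the formula.  Both use the upper tail
of the chi-squared distribution with one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .core_io import MarkerReference
from .embed_cluster import ClusterMarkers

VARIANTS = ("standard", "as_printed")


@dataclass
class OverlapTable:
    """Integer overlap counts T_ij, tissues (rows) x clusters (columns)."""

    table: pd.DataFrame  # index: tissue labels; columns: cluster ids

    def __post_init__(self) -> None:
        vals = self.table.to_numpy()
        if np.any(vals < 0):
            raise ValueError("negative overlap counts")

    @property
    def tissues(self) -> list:
        return list(self.table.index)

    @property
    def clusters(self) -> list:
        return list(self.table.columns)


@dataclass
class ChiSqResult:
    """One rank of the overlap test for one cluster."""

    rank: int
    tissue: str
    O1: float
    E1: float
    O2: float
    E2: float
    statistic: float
    variant: str
    p: float
    p_corrected: float
    significant: bool
    tie: bool = False
    df: int = 1


@dataclass
class AnnotationResult:
    """Per-cluster ordered significant tissue labels and test records."""

    labels: dict  # cluster -> list of tissue labels in rank order
    results: dict  # cluster -> list of ChiSqResult
    alpha: float

    def primary(self, cluster) -> str:
        lab = self.labels.get(cluster, [])
        return lab[0] if lab else "unassigned"

    @property
    def primary_labels(self) -> dict:
        return {c: self.primary(c) for c in self.labels}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.results:
            for r in self.results[c]:
                rows.append(
                    (
                        c,
                        r.rank,
                        r.tissue,
                        r.O1,
                        r.E1,
                        r.O2,
                        r.E2,
                        r.statistic,
                        r.p,
                        r.p_corrected,
                        r.significant,
                        r.tie,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "cluster",
                "rank",
                "tissue",
                "O1",
                "E1",
                "O2",
                "E2",
                "chisq",
                "p",
                "p_corrected",
                "significant",
                "tie",
            ],
        )


def build_overlap_table(cm, ref: MarkerReference) -> OverlapTable:
    """Count |M_i intersect S_j| for every tissue i and cluster j.

    ``cm`` may be a :class:`ClusterMarkers` or a mapping cluster -> gene
    set.  Genes absent from the reference contribute to no cell of the
    table.
    """
    sets = cm.sets if isinstance(cm, ClusterMarkers) else dict(cm)
    if not sets:
        raise ValueError("no cluster marker sets")
    clusters = sorted(sets)
    tissues = sorted(ref.sets)
    data = np.zeros((len(tissues), len(clusters)), dtype=int)
    for j, c in enumerate(clusters):
        s = set(sets[c])
        if not s:
            warnings.warn(f"cluster {c} has an empty marker set")
        for i, t in enumerate(tissues):
            data[i, j] = len(ref.sets[t] & s)
    return OverlapTable(pd.DataFrame(data, index=tissues, columns=clusters))


def chisq_overlap(column, n_tissues: int | None = None, variant: str = "standard") -> ChiSqResult:
    """Test the largest overlap of one cluster column against uniformity.

    Parameters
    ----------
    column
        Mapping or Series of tissue -> overlap count for one cluster.
    n_tissues
        The number N of tissues in the current family (defaults to the
        column length).  Must be >= 2.
    variant
        ``standard`` (Pearson, denominator E) or ``as_printed``
        (denominator E^2).

    Ties for the largest overlap are broken by lexicographic tissue
    label and flagged.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if isinstance(column, pd.Series):
        column = column.to_dict()
    tissues = sorted(column)
    counts = np.array([float(column[t]) for t in tissues])
    n = len(tissues) if n_tissues is None else int(n_tissues)
    if n < 2:
        raise ValueError("chisq_overlap requires N >= 2 tissues")

    total = counts.sum()
    top = counts.max() if len(counts) else 0.0
    tie = int((counts == top).sum()) > 1 if total > 0 else False
    imax = int(np.argmax(counts)) if len(counts) else 0
    tissue = tissues[imax] if tissues else ""

    if total <= 0:
        return ChiSqResult(
            rank=1, tissue=tissue, O1=0.0, E1=0.0, O2=0.0, E2=0.0,
            statistic=0.0, variant=variant, p=1.0, p_corrected=1.0,
            significant=False, tie=False,
        )

    O1 = top
    E1 = total / n
    O2 = total - top
    E2 = total * (n - 1) / n
    if variant == "standard":
        stat = (O1 - E1) ** 2 / E1 + (O2 - E2) ** 2 / E2
    else:
        stat = (O1 - E1) ** 2 / E1**2 + (O2 - E2) ** 2 / E2**2
    p = float(scipy.stats.chi2.sf(stat, df=1))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    p_corr = min(1.0, n * p)
    return ChiSqResult(
        rank=1, tissue=tissue, O1=float(O1), E1=float(E1), O2=float(O2),
        E2=float(E2), statistic=float(stat), variant=variant, p=p,
        p_corrected=p_corr, significant=False, tie=tie,
    )


def annotate_clusters(
    T: OverlapTable,
    alpha: float = 0.01,
    max_rank: int = 3,
    variant: str = "standard",
) -> AnnotationResult:
    """Iterative rank-1..max_rank assignment of tissues to clusters.

    At each rank the current argmax tissue is tested; if its corrected
    p-value is below ``alpha`` the tissue is recorded, its row removed
    from the cluster's column, N decremented, and the next rank tested.
    Otherwise iteration stops.  A cluster whose rank-1 test fails is
    left "unassigned".
    """
    labels: dict = {}
    results: dict = {}
    for c in T.clusters:
        col = {t: int(v) for t, v in T.table[c].items()}
        labels[c], results[c] = [], []
        for k in range(1, max_rank + 1):
            if len(col) < 2 or sum(col.values()) == 0:
                break
            res = chisq_overlap(col, n_tissues=len(col), variant=variant)
            res.rank = k
            res.significant = res.p_corrected < alpha
            results[c].append(res)
            if not res.significant:
                break
            labels[c].append(res.tissue)
            del col[res.tissue]
    return AnnotationResult(labels=labels, results=results, alpha=alpha)


def group_clusters(primary_labels, mapping) -> dict:
    """Map per-cluster primary labels into coarser groups.

    ``primary_labels`` may be an :class:`AnnotationResult` or a mapping
    cluster -> label.  Unassigned clusters pass through unchanged; an
    assigned label missing from ``mapping`` is an error.
    """
    if isinstance(primary_labels, AnnotationResult):
        primary_labels = primary_labels.primary_labels
    out = {}
    missing = []
    for c, lab in primary_labels.items():
        if lab == "unassigned":
            out[c] = "unassigned"
        elif lab in mapping:
            out[c] = mapping[lab]
        else:
            missing.append(lab)
    if missing:
        raise KeyError(f"unmapped label {', '.join(sorted(set(missing)))}")
    return out
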