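"""Quality-control filtering and protoplasting-induced gene derivation.

Three single-cell filters are applied in a single pass: removal of
protoplasting-induced genes, removal of genes detected in too few
cells, and removal of low-quality cells (low total UMIs, or an excess
of organellar UMIs).  Cell-level criteria are evaluated on the
original per-cell totals so that gene filtering cannot change a cell's
QC verdict.

Induced genes are derived from a paired bulk protoplast/control count
table: per-gene log2 fold-change and Welch's t-test on log-CPM with
Benjamini-Hochberg adjustment, selecting genes with adjusted p below
``alpha`` and log2 fold-change strictly above ``lfc_min``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core_io import CountMatrix, GeneList


class DesignError(ValueError):
    """The bulk design does not contain both conditions."""


class EmptyMatrixError(ValueError):
    """Filtering removed every cell."""

    def __init__(self, report):
        self.report = report
        super().__init__(f"all cells removed by QC: {report}")


@dataclass
class QCReport:
    """Per-axis accounting of what the filters removed."""

    n_genes_removed_induced: int
    n_genes_removed_low_detection: int
    n_cells_removed_low_umi: int
    n_cells_removed_organellar: int
    n_cells_in: int
    n_genes_in: int
    n_cells_out: int
    n_genes_out: int

    def __post_init__(self) -> None:
        assert (
            self.n_genes_removed_induced
            + self.n_genes_removed_low_detection
            + self.n_genes_out
            == self.n_genes_in
        )
        assert (
            self.n_cells_removed_low_umi
            + self.n_cells_removed_organellar
            + self.n_cells_out
            == self.n_cells_in
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.__dict__.items()), columns=["metric", "value"]
        )


def induced_gene_table(bulk: pd.DataFrame, design) -> pd.DataFrame:
    """Per-gene differential table for the protoplast vs control pair.

    Counts are converted to log2 CPM (per-sample total-count size
    factors, pseudocount 1), tested with Welch's t-test, and BH-adjusted.
    """
    design = np.asarray(design, dtype=object)
    if len(design) != bulk.shape[1]:
        raise DesignError("design length does not match number of samples")
    is_p = design == "protoplast"
    is_c = design == "control"
    if is_p.sum() < 2 or is_c.sum() < 2:
        raise DesignError("need >= 2 replicates per condition (protoplast/control)")

    counts = bulk.to_numpy(dtype=float)
    cpm = counts / counts.sum(axis=0, keepdims=True) * 1e6
    logcpm = np.log2(cpm + 1.0)

    xp, xc = logcpm[:, is_p], logcpm[:, is_c]
    lfc = xp.mean(axis=1) - xc.mean(axis=1)
    t, p = scipy.stats.ttest_ind(xp, xc, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    padj = scipy.stats.false_discovery_control(p, method="bh")
    return pd.DataFrame(
        {"gene": bulk.index, "log_fc": lfc, "p": p, "p_adj": padj}
    ).set_index("gene")


def select_induced(table: pd.DataFrame, lfc_min: float = 2.0, alpha: float = 0.05) -> GeneList:
    """Apply the selection rule: p_adj < alpha AND log_fc > lfc_min (strict)."""
    keep = (table["p_adj"] < alpha) & (table["log_fc"] > lfc_min)
    return GeneList(tuple(table.index[keep]), purpose="induced")


def derive_induced_genes(
    bulk: pd.DataFrame, design, lfc_min: float = 2.0, alpha: float = 0.05
) -> GeneList:
    """Derive protoplasting-induced genes from a bulk pair."""
    return select_induced(induced_gene_table(bulk, design), lfc_min, alpha)


def filter_matrix(
    m: CountMatrix,
    induced: GeneList | None = None,
    min_cells: int = 4,
    min_umi: int = 500,
    max_organellar_frac: float = 0.01,
):
    """Apply the three QC filters and return (filtered matrix, report).

    Removes, in order: (1) induced genes; (2) genes detected (count > 0)
    in fewer than ``min_cells`` cells, evaluated on the post-(1) matrix
    over all cells; (3) cells with total UMI < ``min_umi``; (4) cells
    whose organellar UMI fraction strictly exceeds
    ``max_organellar_frac``.  Cell totals and organellar fractions are
    computed on the original matrix, before any gene removal.
    """
    induced_set = set(induced) if induced is not None else set()

    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    org_counts = np.asarray(m.counts[:, m.organellar_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        org_frac = np.where(totals > 0, org_counts / np.maximum(totals, 1), 0.0)

    keep_gene = np.array([g not in induced_set for g in m.genes])
    n_induced_removed = int((~keep_gene).sum())

    detection = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    low_det = keep_gene & (detection < min_cells)
    keep_gene &= ~low_det

    low_umi = totals < min_umi
    high_org = ~low_umi & (org_frac > max_organellar_frac)
    keep_cell = ~low_umi & ~high_org

    report = QCReport(
        n_genes_removed_induced=n_induced_removed,
        n_genes_removed_low_detection=int(low_det.sum()),
        n_cells_removed_low_umi=int(low_umi.sum()),
        n_cells_removed_organellar=int(high_org.sum()),
        n_cells_in=m.n_cells,
        n_genes_in=m.n_genes,
        n_cells_out=int(keep_cell.sum()),
        n_genes_out=int(keep_gene.sum()),
    )
    if report.n_cells_out == 0:
        raise EmptyMatrixError(report)
    filtered = m.subset(np.where(keep_cell)[0], np.where(keep_gene)[0])
    return filtered, report
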