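"""Domain types and file I/O for the pipeline.

The pipeline's on-disk currency is the 10X-style triplet layout
(``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``), a two-column
tissue/gene TSV for reference marker sets, and one-gene-per-line text
files for flat gene lists.  Everything is plain text; MatrixMarket
files are read and written through :mod:`scipy.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class InputError(ValueError):
    """A required input file is missing or unreadable."""


class FormatError(ValueError):
    """An input file exists but violates its format contract."""


# default prefixes marking organellar (mitochondrial / plastid) gene ids
ORGANELLAR_PREFIXES = ("MT-", "PT-")


@dataclass
class CountMatrix:
    """Sparse cells x genes UMI count matrix with axis identifiers.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, cells as rows.
    barcodes
        Cell identifiers, one per row, unique.
    genes
        Gene identifiers, one per column, unique.
    organellar_mask
        Per-gene boolean flag marking mitochondrial/plastid genes.
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    genes: np.ndarray
    organellar_mask: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        self.organellar_mask = np.asarray(self.organellar_mask, dtype=bool)
        n, g = self.counts.shape
        if len(self.barcodes) != n:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for {n} matrix rows"
            )
        if len(self.genes) != g:
            raise FormatError(f"{len(self.genes)} genes for {g} matrix columns")
        if len(self.organellar_mask) != g:
            raise FormatError("organellar_mask length != number of genes")
        for name, ids in (("barcode", self.barcodes), ("gene", self.genes)):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {name} identifiers")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer counts")
        self.counts.data = np.round(self.counts.data).astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, cell_idx=None, gene_idx=None) -> "CountMatrix":
        """Return a new matrix restricted to the given row/column indices."""
        cell_idx = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        gene_idx = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        return CountMatrix(
            counts=self.counts[cell_idx][:, gene_idx],
            barcodes=self.barcodes[cell_idx],
            genes=self.genes[gene_idx],
            organellar_mask=self.organellar_mask[gene_idx],
        )


@dataclass
class MarkerReference:
    """Mutually exclusive reference marker sets, one per tissue.

    The disjointness of the sets is an invariant of the annotation
    method (each reference gene votes for exactly one tissue), so the
    constructor rejects any gene listed under two tissues rather than
    silently de-duplicating.
    """

    sets: dict

    def __post_init__(self) -> None:
        if not self.sets:
            raise FormatError("no marker sets")
        clean = {}
        seen: dict = {}
        for tissue in self.sets:
            genes = frozenset(self.sets[tissue])
            if not genes:
                raise FormatError(f"empty marker set for tissue {tissue!r}")
            for g in sorted(genes):
                if g in seen:
                    raise FormatError(
                        f"duplicated marker {g} (in {seen[g]!r} and {tissue!r})"
                    )
                seen[g] = tissue
            clean[tissue] = genes
        self.sets = clean

    @property
    def n_tissues(self) -> int:
        return len(self.sets)

    @property
    def tissues(self) -> list:
        return list(self.sets)


@dataclass
class GeneList:
    """A flat list of unique gene identifiers with a purpose tag."""

    genes: tuple
    purpose: str = "generic"

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if len(set(genes)) != len(genes):
            raise FormatError("duplicate entries in gene list")
        self.genes = genes

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in set(self.genes)


def _organellar_mask(genes: np.ndarray, organellar_genes, prefixes) -> np.ndarray:
    if organellar_genes is not None:
        org = set(organellar_genes)
        return np.array([g in org for g in genes], dtype=bool)
    return np.array(
        [any(str(g).startswith(p) for p in prefixes) for g in genes], dtype=bool
    )


def read_10x_mtx(
    path,
    organellar_genes: Iterable[str] | None = None,
    organellar_prefixes: Sequence[str] = ORGANELLAR_PREFIXES,
) -> CountMatrix:
    """Read a 10X-layout directory into a :class:`CountMatrix`.

    The on-disk convention is genes-as-rows; the returned matrix is
    always oriented cells x genes.  An explicit ``organellar_genes``
    list wins over the prefix rule.
    """
    path = Path(path)
    mtx = path / "matrix.mtx"
    bc = path / "barcodes.tsv"
    ft = path / "features.tsv"
    for f in (mtx, bc, ft):
        if not f.exists():
            raise InputError(f"missing input file: {f}")

    with open(mtx) as fh:
        header = fh.readline()
    if not header.startswith("%%MatrixMarket"):
        raise FormatError(f"{mtx} is not a MatrixMarket file")
    fields = header.lower().split()
    if "coordinate" not in fields:
        raise FormatError("only coordinate MatrixMarket matrices are supported")
    if "complex" in fields or "pattern" in fields:
        raise FormatError("complex/pattern MatrixMarket matrices are not supported")

    mat = sp.coo_matrix(scipy.io.mmread(mtx))

    def _read_ids(path):
        try:
            return pd.read_csv(path, sep="\t", header=None)[0].astype(str).to_numpy()
        except pd.errors.EmptyDataError:
            return np.array([], dtype=object)

    barcodes = _read_ids(bc)
    genes = _read_ids(ft)

    n_genes, n_cells = len(genes), len(barcodes)
    if mat.shape == (n_genes, n_cells):
        mat = mat.T
    elif mat.shape != (n_cells, n_genes):
        raise FormatError(
            f"matrix.mtx shape {mat.shape} matches neither "
            f"(genes={n_genes}, barcodes={n_cells}) nor its transpose"
        )
    if mat.data.size and (np.any(mat.data < 0) or not np.allclose(mat.data, np.round(mat.data))):
        raise FormatError("matrix.mtx contains negative or non-integer entries")

    mask = _organellar_mask(np.asarray(genes, dtype=object), organellar_genes, organellar_prefixes)
    return CountMatrix(sp.csr_matrix(mat), barcodes, genes, mask)


def write_10x_mtx(m: CountMatrix, path) -> None:
    """Write a :class:`CountMatrix` as a 10X-layout directory.

    Triplets are emitted genes-as-rows in row-major (gene, cell) order
    so that output is deterministic for a given matrix.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    gx = sp.csr_matrix(m.counts.T)  # genes x cells, row-major triplet order
    gx.sort_indices()
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(gx), field="integer")
    with open(path / "barcodes.tsv", "w") as fh:
        fh.writelines(f"{b}\n" for b in m.barcodes)
    with open(path / "features.tsv", "w") as fh:
        fh.writelines(f"{g}\n" for g in m.genes)


def read_marker_sets(path) -> MarkerReference:
    """Read a two-column (tissue <TAB> gene) TSV into a :class:`MarkerReference`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing marker file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["tissue", "gene"], dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError("no marker sets") from None
    if df.empty:
        raise FormatError("no marker sets")
    sets: dict = {}
    dup_within = df.duplicated()
    if dup_within.any():
        g = df[dup_within].iloc[0]["gene"]
        raise FormatError(f"duplicated marker {g}")
    for tissue, sub in df.groupby("tissue", sort=True):
        sets[tissue] = set(sub["gene"])
    return MarkerReference(sets)


def write_marker_sets(ref: MarkerReference, path) -> None:
    rows = [(t, g) for t in sorted(ref.sets) for g in sorted(ref.sets[t])]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gene_list(path, purpose: str = "generic") -> GeneList:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing gene list: {path}")
    genes = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return GeneList(tuple(genes), purpose=purpose)


def write_gene_list(gl: GeneList, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gl.genes))
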