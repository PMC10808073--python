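"""Synthetic single-cell atlas generator with planted ground truth.

The generator emulates the structures the downstream pipeline is built
to recover: K cell types with mutually exclusive marker genes, a rooted
branched lineage (an initial population splitting into cortex,
endodermis and exodermis, with a detached meristem anchor population),
gamma-Poisson (negative binomial) UMI counts, a designated organellar
gene subset with per-cell organellar fractions, low-UMI junk droplets,
protoplasting-induced genes elevated uniformly across all cells, and a
set of genes restricted to the terminal segment of one branch.  A paired
bulk protoplast/control experiment over the same gene universe feeds the
induced-gene derivation.

All randomness flows from one master seed; each stage draws from a
deterministically derived child stream, so identical configurations
yield bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CountMatrix


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


DEFAULT_TOPOLOGY: Mapping[str, Sequence[str]] = {
    "initial": ("cortex", "endodermis", "exodermis")
}


@dataclass
class SimConfig:
    """Parameters of the synthetic atlas.

    The defaults describe the study conditions used throughout the test
    suite: 5 cell types x 200 cells, 2,000 genes, 10 markers per type at
    8-fold enrichment, negative binomial dispersion theta = 10, and a
    log-normal library-size distribution around 5,000 UMIs per cell.
    """

    # cell population ----------------------------------------------------
    n_cells_per_type: int = 200
    topology: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_TOPOLOGY)
    )
    anchor_types: Sequence[str] = ("meristem",)
    trunk_span: float = 0.3  # pseudotime of the branch point

    # gene universe ------------------------------------------------------
    n_genes: int = 2000
    markers_per_type: int = 10
    marker_fold: float = 8.0
    branch_onset: float = 0.3  # fraction of marker effect at branch start
    anchor_progenitor_effect: float = 0.15  # trunk signature in anchor cells
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    dispersion: float = 10.0  # NB theta: var = mu + mu^2/theta

    # library sizes ------------------------------------------------------
    library_log_mean: float = math.log(5000.0)
    library_log_sd: float = 0.3

    # organellar genes ---------------------------------------------------
    n_organellar: int = 20
    organellar_beta: tuple = (1.0, 99.0)
    organellar_high_beta: tuple = (5.0, 45.0)
    organellar_high_prob: float = 0.02

    # junk droplets ------------------------------------------------------
    n_junk_cells: int = 50
    junk_umi_range: tuple = (50, 300)

    # protoplasting-induced genes ---------------------------------------
    n_induced_genes: int = 50
    induced_log2_fc: float = 2.5
    bulk_depth: float = 1e6
    bulk_dispersion: float = 50.0

    # branch-tip-restricted genes ---------------------------------------
    n_tip_genes: int = 20
    tip_branch: str = "exodermis"
    tip_quantile: float = 0.2  # terminal fraction of the branch
    tip_fold: float = 8.0
    tip_leak: float = 0.02  # relative expression outside the tip

    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.topology) != 1:
            raise ConfigError("topology must have a single trunk type")
        self.root_type = next(iter(self.topology))
        self.branch_types = tuple(self.topology[self.root_type])
        if not self.branch_types:
            raise ConfigError("topology must branch into at least one type")
        self.types = tuple(self.anchor_types) + (self.root_type,) + self.branch_types
        if len(set(self.types)) != len(self.types):
            raise ConfigError("duplicate cell-type labels")
        if self.tip_branch not in self.branch_types:
            raise ConfigError(f"tip_branch {self.tip_branch!r} is not a branch type")
        n_special = (
            self.markers_per_type * len(self.types)
            + self.n_tip_genes
            + self.n_induced_genes
            + self.n_organellar
        )
        if n_special > self.n_genes:
            raise ConfigError(
                f"gene budget exceeded: {n_special} structured genes "
                f"> n_genes={self.n_genes}"
            )
        if not 0 < self.trunk_span < 1:
            raise ConfigError("trunk_span must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated atlas."""

    cell_types: np.ndarray  # per cell, includes "junk"
    pseudotime: np.ndarray  # per cell in [0, 1]; NaN for junk
    branch: np.ndarray  # terminal type, "trunk", "anchor" or "junk"
    marker_sets: dict  # type -> frozenset of gene ids
    induced_genes: tuple
    organellar_genes: tuple
    tip_genes: tuple
    tip_branch: str

    def cell_table(self, barcodes) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": barcodes,
                "cell_type": self.cell_types,
                "pseudotime": self.pseudotime,
                "branch": self.branch,
            }
        )

    def gene_table(self) -> pd.DataFrame:
        rows = []
        for t in sorted(self.marker_sets):
            for g in sorted(self.marker_sets[t]):
                rows.append((g, "marker", t))
        rows += [(g, "induced", "") for g in self.induced_genes]
        rows += [(g, "organellar", "") for g in self.organellar_genes]
        rows += [(g, "tip", self.tip_branch) for g in self.tip_genes]
        return pd.DataFrame(rows, columns=["gene", "role", "annotation"])


def _rng(cfg_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg_seed, spawn_key=(stage,)))


def _gene_plan(cfg: SimConfig):
    """Deterministic gene layout shared by the atlas and the bulk pair.

    Returns ids, per-gene base abundances, and index arrays for each
    planted role.
    """
    rng = _rng(cfg.seed, 0)
    n_reg = cfg.n_genes - cfg.n_organellar
    ids = np.array(
        [f"G{i:04d}" for i in range(n_reg)]
        + [f"MT-G{i:04d}" for i in range(cfg.n_organellar)],
        dtype=object,
    )
    base = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)

    pos = 0
    marker_idx = {}
    for t in cfg.types:
        marker_idx[t] = np.arange(pos, pos + cfg.markers_per_type)
        pos += cfg.markers_per_type
    tip_idx = np.arange(pos, pos + cfg.n_tip_genes)
    pos += cfg.n_tip_genes
    induced_idx = np.arange(pos, pos + cfg.n_induced_genes)
    org_idx = np.arange(n_reg, cfg.n_genes)
    return ids, base, marker_idx, tip_idx, induced_idx, org_idx


def _marker_effect(cfg: SimConfig, t: str, types, pt):
    """Per-cell effect (0..1) of type ``t``'s markers.

    Anchor markers are fully on within their own type only.  Trunk
    markers ramp up along the trunk (partial onset at the origin, full
    effect at the branch point) and fade out by mid-branch; branch
    markers ramp from a partial onset at the branch point to full
    effect at the tip.  Expression therefore varies smoothly with
    pseudotime along every path.  Anchor (meristematic) cells carry a
    weak trunk signature — they are the progenitor state upstream of
    the trunk origin — which keeps them transcriptionally adjacent to
    the start of the lineage without registering as trunk markers.
    """
    e = np.zeros(len(types))
    onset = cfg.branch_onset
    if t in cfg.anchor_types:
        e[types == t] = 1.0
    elif t == cfg.root_type:
        own = types == t
        e[own] = np.clip(onset + (1.0 - onset) * pt[own] / cfg.trunk_span, 0.0, 1.0)
        e[np.isin(types, cfg.anchor_types)] = cfg.anchor_progenitor_effect
        on_branch = np.isin(types, cfg.branch_types)
        prog = (pt[on_branch] - cfg.trunk_span) / (1 - cfg.trunk_span)
        e[on_branch] = np.clip(1.0 - 2.0 * prog, 0.0, 1.0)
    elif t in cfg.branch_types:
        own = types == t
        prog = (pt[own] - cfg.trunk_span) / (1 - cfg.trunk_span)
        e[own] = np.clip(onset + (1 - onset) * prog, 0.0, 1.0)
    return e


def simulate_atlas(cfg: SimConfig):
    """Generate a synthetic atlas and its ground truth.

    Returns
    -------
    (CountMatrix, SyntheticTruth)
        Gamma-Poisson counts (cells x genes) and the planted truth.
    """
    ids, base, marker_idx, tip_idx, induced_idx, org_idx = _gene_plan(cfg)
    rng_cells = _rng(cfg.seed, 1)
    rng_counts = _rng(cfg.seed, 2)

    # --- cell population and true pseudotime ---------------------------
    types_list, pt_list, branch_list = [], [], []
    for t in cfg.types:
        types_list += [t] * cfg.n_cells_per_type
        if t in cfg.anchor_types:
            pt = np.zeros(cfg.n_cells_per_type)
            branch_list += ["anchor"] * cfg.n_cells_per_type
        elif t == cfg.root_type:
            pt = rng_cells.uniform(0, cfg.trunk_span, cfg.n_cells_per_type)
            branch_list += ["trunk"] * cfg.n_cells_per_type
        else:
            pt = rng_cells.uniform(cfg.trunk_span, 1.0, cfg.n_cells_per_type)
            branch_list += [t] * cfg.n_cells_per_type
        pt_list.append(pt)

    n_real = cfg.n_cells_per_type * len(cfg.types)
    # junk droplets copy a random real type's profile at tiny depth
    junk_src = rng_cells.choice(len(cfg.types), cfg.n_junk_cells)
    junk_types = [cfg.types[i] for i in junk_src]
    junk_pt = rng_cells.uniform(0, 1, cfg.n_junk_cells)

    types = np.array(types_list + junk_types, dtype=object)
    truth_types = np.array(types_list + ["junk"] * cfg.n_junk_cells, dtype=object)
    pt = np.concatenate(pt_list + [junk_pt])
    truth_pt = pt.copy()
    truth_pt[n_real:] = np.nan
    branch = np.array(branch_list + ["junk"] * cfg.n_junk_cells, dtype=object)
    n_cells = len(types)

    # --- expected expression weights -----------------------------------
    w = np.tile(base, (n_cells, 1))
    for t in cfg.types:
        e = _marker_effect(cfg, t, types, pt)
        w[:, marker_idx[t]] *= (1.0 + (cfg.marker_fold - 1.0) * e)[:, None]

    prog = (pt - cfg.trunk_span) / (1 - cfg.trunk_span)
    in_tip = (types == cfg.tip_branch) & (prog >= 1 - cfg.tip_quantile)
    w[:, tip_idx] *= cfg.tip_leak
    w[np.ix_(in_tip, tip_idx)] *= cfg.tip_fold / cfg.tip_leak

    w[:, induced_idx] *= 2.0 ** cfg.induced_log2_fc

    # organellar share: rescale organellar weights so their expected
    # fraction of the library equals the per-cell draw
    a, b = cfg.organellar_beta
    frac = rng_cells.beta(a, b, n_cells)
    hi = rng_cells.uniform(size=n_cells) < cfg.organellar_high_prob
    a2, b2 = cfg.organellar_high_beta
    frac[hi] = rng_cells.beta(a2, b2, hi.sum())
    if cfg.n_organellar:
        rest = np.delete(w, org_idx, axis=1).sum(axis=1)
        org_base = w[:, org_idx].sum(axis=1)
        scale = frac / (1 - frac) * rest / org_base
        w[:, org_idx] *= scale[:, None]

    # --- library sizes and gamma-Poisson sampling ----------------------
    lib = rng_cells.lognormal(cfg.library_log_mean, cfg.library_log_sd, n_cells)
    lo, hi_umi = cfg.junk_umi_range
    lib[n_real:] = rng_cells.uniform(lo, hi_umi, cfg.n_junk_cells)

    mu = w * (lib / w.sum(axis=1))[:, None]
    lam = rng_counts.gamma(cfg.dispersion, mu / cfg.dispersion)
    counts = rng_counts.poisson(lam)

    barcodes = np.array([f"CELL{i:04d}" for i in range(n_cells)], dtype=object)
    mask = np.zeros(cfg.n_genes, dtype=bool)
    mask[org_idx] = True
    cm = CountMatrix(sp.csr_matrix(counts), barcodes, ids, mask)

    truth = SyntheticTruth(
        cell_types=truth_types,
        pseudotime=truth_pt,
        branch=branch,
        marker_sets={t: frozenset(ids[marker_idx[t]]) for t in cfg.types},
        induced_genes=tuple(ids[induced_idx]),
        organellar_genes=tuple(ids[org_idx]),
        tip_genes=tuple(ids[tip_idx]),
        tip_branch=cfg.tip_branch,
    )
    return cm, truth


def simulate_bulk_pair(cfg: SimConfig, n_reps: int = 4):
    """Simulate a bulk protoplast vs control pair over the atlas genes.

    Induced genes carry a true log2 fold-change of ``cfg.induced_log2_fc``
    in the protoplast samples; all other genes are null.

    Returns
    -------
    (pandas.DataFrame, list of str)
        A genes x samples count table and the per-sample condition
        labels (``protoplast`` / ``control``).
    """
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2 per condition")
    ids, base, _, _, induced_idx, _ = _gene_plan(cfg)
    rng = _rng(cfg.seed, 3)

    w_ctrl = base.copy()
    w_prot = base.copy()
    w_prot[induced_idx] *= 2.0 ** cfg.induced_log2_fc

    cols, names, design = [], [], []
    for cond, wvec in (("protoplast", w_prot), ("control", w_ctrl)):
        mu = wvec / wvec.sum() * cfg.bulk_depth
        for r in range(n_reps):
            lam = rng.gamma(cfg.bulk_dispersion, mu / cfg.bulk_dispersion)
            cols.append(rng.poisson(lam))
            names.append(f"{cond}_{r + 1}")
            design.append(cond)
    table = pd.DataFrame(np.column_stack(cols), index=ids, columns=names)
    table.index.name = "gene"
    return table, design
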