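# exoatlas

A single-cell RNA-seq analysis pipeline for annotating a branched root
atlas — built around the workflow used to map the suberizing exodermis
of the tomato root at cellular resolution.

Droplet scRNA-seq of plant roots poses three linked problems that this
package addresses end to end:

1. **Quality control.** Protoplasting (enzymatic cell-wall digestion)
   artifactually induces genes that must be identified from a paired
   bulk protoplast/control experiment and removed; low-UMI droplets and
   cells dominated by organellar transcripts must be filtered.
2. **Cluster annotation.** Unsupervised clusters are assigned cell-type
   identities by intersecting their detected marker genes S_j with
   mutually exclusive reference tissue marker sets M_i.  For each
   cluster the overlap table T_ij = |M_i ∩ S_j| is tested: with
   O1 = max_i T_ij, E1 = (Σ_i T_ij)/N, O2 = Σ_{i≠imax} T_ij and
   E2 = (Σ_i T_ij)(N−1)/N, the two-cell goodness-of-fit statistic
   χ² = Σ_{i=1,2} (O_i − E_i)²/E_i (df = 1, Bonferroni-corrected over
   the N tissues) decides whether the top overlap is significant; the
   test is repeated on the second- and third-highest overlaps until the
   corrected p exceeds 0.01.  A published variant that divides by E_i²
   is also provided (`variant="as_printed"`).
3. **Pseudotime.** The ground-tissue lineage (initial → cortex /
   endodermis / exodermis, anchored by the root meristem) is re-embedded
   and re-clustered; cluster centroids become milestones joined by a
   Euclidean minimum spanning tree rooted in the meristem.  Cells are
   projected onto the tree, pseudotime is geodesic distance from the
   root, and genes are scored per branch by Spearman correlation with
   pseudotime and by a tip-restriction ratio that nominates genes
   confined to a branch terminus — the signature of suberin biosynthesis
   genes at the end of the exodermal trajectory.

Because the original raw data are not required, the package ships a
synthetic atlas generator (`exoatlas.simulate`) that plants known cell
types, marker sets, a branched trajectory, organellar fractions,
low-quality droplets, protoplasting-induced genes and tip-restricted
genes, so that every stage has a recovery test with known truth.

## Worked example

```python
from exoatlas import chisq_overlap
r = chisq_overlap({"exodermis": 20, "endodermis": 15, "cortex": 1, "epidermis": 0})
print(f"rank-1 tissue: {r.tissue}")
print(f"chi2 = {r.statistic:.3f}, p = {r.p:.2e}, Bonferroni-corrected p = {r.p_corrected:.2e}")
```

```
rank-1 tissue: exodermis
chi2 = 17.926, p = 2.30e-05, Bonferroni-corrected p = 9.19e-05
```

The overlap of 20 exodermis reference markers in this cluster's marker
set is far above the uniform expectation of 9 (36 overlapping genes
across 4 tissues), so the cluster is annotated exodermis at rank 1.

Running the whole pipeline on a synthetic atlas (5 cell types × 200
cells, 2,000 genes) and scoring it against the planted truth:

```python
from exoatlas.evaluation import run_atlas_recovery
rec = run_atlas_recovery(seed=1)
print(f"clusters: {rec.n_clusters}  correctly annotated: {rec.n_correct}")
for b, rho in sorted(rec.branch_spearman.items()):
    print(f"pseudotime Spearman rho, {b}: {rho:.2f}")
print(f"tip-gene recall (top-2k): {rec.tip_recall:.2f}")
```

```
clusters: 6  correctly annotated: 6
pseudotime Spearman rho, cortex: 0.88
pseudotime Spearman rho, endodermis: 0.81
pseudotime Spearman rho, exodermis: 0.92
tip-gene recall (top-2k): 1.00
```

All six clusters receive their majority cell type, the planted branch
orders are recovered with rank correlation ≥ 0.8, and all 20 genes
planted in the terminal 20% of the exodermis branch appear in the top
40 of the tip-restriction ranking.

A shell interface mirrors the library (`exoatlas simulate`, `qc`,
`cluster`, `markers`, `annotate`, `enrich`, `rwc`, and `run-all` for the
whole chain on a YAML config with a JSON run manifest); see
`exoatlas --help`.

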