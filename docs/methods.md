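# Methods

## Scope and data model

The pipeline operates on sparse cells × genes UMI count matrices
(10X-style MatrixMarket triplet layout on disk) with per-gene
organellar flags, reference marker sets given as a two-column
tissue/gene TSV, and flat gene lists.  Reference marker sets are
required to be mutually exclusive: each reference gene votes for
exactly one tissue, which is what makes the overlap table below
interpretable; construction fails loudly on any duplicated gene.

## Quality control

Protoplasting-induced genes are derived from a paired bulk
protoplast/control experiment: counts are converted to log2 CPM
(per-sample total-count size factors, pseudocount 1), each gene is
tested with Welch's t-test and adjusted by Benjamini–Hochberg, and
genes with adjusted p < 0.05 **and** log2 fold-change strictly
greater than 2 are selected.  Welch's t on log-CPM is a transparent,
dependency-free stand-in for a negative-binomial GLM; with ≥ 4
replicates per arm and the planted 2.5 log2-unit effects it recovers
the induced set with recall ≥ 0.9 and false-discovery proportion
≤ 0.1 (measured by the acceptance script).

Single-cell filtering then removes, in order: (1) the induced genes;
(2) genes detected (count > 0) in fewer than 4 cells, evaluated on the
post-(1) matrix; (3) cells with fewer than 500 total UMIs; (4) cells
whose organellar UMI fraction strictly exceeds 1%.  All cell-level
criteria use the *original* per-cell totals, computed before any gene
removal — gene filtering must not change a cell's QC verdict, and the
organellar fraction is a property of the droplet, not of the retained
gene set.  Organellar genes themselves are retained (they are a QC
covariate, not a removal target).  Boundary semantics are strict and
tested: 499 UMIs removed / 500 kept; detection in 3 cells removed / 4
kept; organellar fraction exactly 1% kept / above removed.

## Normalization, embedding, clustering, markers

Normalization is ln(1 + c·10⁴/total) per cell (zeros preserved),
followed by centered PCA (50 components by default, deterministic sign
convention: the largest-magnitude loading of each component is made
positive).  Clustering is Leiden community detection
(RBConfiguration, seeded) on an undirected kNN graph (k = 20) built on
the first 35 components.  The pipeline default resolution is 1.0; at
coarser resolutions the trunk population and the earliest branch cells
merge into one cluster that genuinely straddles the branch point,
which is a property of a continuous trajectory rather than an error,
but finer granularity keeps boundary clusters type-pure.

Marker detection tests each cluster against all other cells.  A gene
is tested only if its expressed fraction reaches 0.1 in at least one
of the two groups and its log fold-change — ln of the ratio of
de-logged group means with pseudocount 1e-9 — is positive and at least
0.25.  P-values come from the two-sided Wilcoxon rank-sum test
(normal approximation with tie correction and continuity) and are
Bonferroni-adjusted over the genes tested for that cluster; the
cluster's marker set S_j is the genes with adjusted p < 0.05.  The
per-cluster Bonferroni family (rather than all genes in the dataset)
is the least-conservative reading consistent with "adjustment over
tested genes"; the whole gate sequence is verified against an
independent per-gene loop.

## Overlap-based cluster annotation

Given reference sets M_i (i = 1…N) and cluster sets S_j, the overlap
table is T_ij = |M_i ∩ S_j|.  For one cluster column with total
T = Σ_i T_ij:

- O1 = max_i T_ij, E1 = T/N,
- O2 = T − O1, E2 = T·(N−1)/N.

E2 is chosen so that expectations sum to the observed total, making
the pair (O1, O2) a two-cell goodness-of-fit test with one degree of
freedom — the only choice consistent with E1 and df = 1.  The default
statistic is Pearson's Σ(O−E)²/E; a second variant dividing by E²
(`as_printed`) reproduces a published, dimensionally non-standard
display of the formula, and both are exposed so their disagreement is
measurable.  Both use the upper tail of χ²(1); the Bonferroni family
is the N tissues currently in play for the cluster.

Assignment is iterative: test the argmax tissue; if the corrected p is
below 0.01, record it, delete its row, decrement N and repeat, up to
three ranks.  The first recorded tissue is the primary label;
a cluster whose rank-1 test fails is "unassigned".  Ties for the
argmax are broken lexicographically and flagged.  Decrementing N
between ranks makes each re-test a test of the *current* maximum,
which is what "repeat for the second and third highest" requires.

## Trajectory

The lineage subset (all clusters annotated with a lineage type) is
re-embedded by PCA and re-clustered at resolution 0.8 (k = 20), giving
coarse milestones — approximately one per population plus the branch
tip.  Milestone centroids are joined by a Euclidean minimum spanning
tree (Kruskal, ties broken by edge id order, duplicate centroids
rejected), rooted at the milestone with the largest share of
meristem-annotated cells.

Cells are projected orthogonally onto their nearest tree edge.
Projections are clamped to the segment at internal milestones but may
extrapolate past a degree-1 (terminal) milestone: without this, every
cell beyond a branch-tip centroid would collapse onto the centroid and
tie in pseudotime, destroying the ordering of exactly the cells the
tip analysis cares about.  Pseudotime is the geodesic tree distance
from the root to the projection, floored at zero; a cell's branch is
the leaf whose root-path contains its edge.

The centroid/projection space is the first 10 principal components by
default rather than a 2-D nonlinear embedding: with three branches
plus a trunk and an anchor, 2-D projections fold arms onto one
another, and 10 linear dimensions keep the tree deterministic and
reproducible bit-for-bit across reruns.  A 2-D UMAP embedding remains
available (`embedding="umap"`).

Per-branch feature scores are transparent by construction: Spearman
correlation of each gene with pseudotime over the branch's cells;
milestone marker statistics via the same marker detector; and
tip_restriction(g, b) = mean expression of g in the terminal 20%
(by pseudotime quantile) of branch b divided by its mean expression in
all other lineage cells (+ε, ε = 1e-6).  Candidate tip genes are
ranked by tip restriction, ties by correlation.  These replace
random-forest feature importances with deterministic quantities that
an exhaustive oracle can check.

## Enrichment and water status

Module-vs-gene-set enrichment is Fisher's exact test on the 2×2
membership table within an explicit gene universe, reported with the
sample (cross-product) odds ratio a·d/(b·c) (infinite when b·c = 0 and
a·d > 0; the conditional MLE is deliberately not used, as the sample
estimate is the convention for reporting module enrichments).  The
two-sided p sums hypergeometric point probabilities no larger than the
observed table's (with the standard 1+1e-7 relative slack) and is
verified against an explicit summation oracle to 1e-10.

Relative water content is the standard formula
RWC (%) = (TFW − DW) × 100 / (TW − DW), defined for TW > DW.

## Synthetic atlas generator

The generator defines the study conditions used by every recovery
test: five populations (meristem anchor, initial, cortex, endodermis,
exodermis) × 200 cells, 2,000 genes, 10 mutually exclusive markers per
type at 8-fold enrichment, gamma-Poisson counts with dispersion
θ = 10 (var = μ + μ²/θ), log-normal library sizes
(median 5,000 UMIs, σ_log = 0.3), 20 organellar genes with per-cell
organellar fractions Beta(1, 99) (2% of cells Beta(5, 45), so the >1%
filter has true positives), 50 junk droplets of 50–300 UMIs, 50
protoplasting-induced genes elevated 2^2.5-fold uniformly across
cells (and in the bulk protoplast arm), and 20 tip genes expressed
8-fold in the terminal 20% of the exodermis branch and at 2% baseline
elsewhere.

Pseudotime is uniform: the initial population spans [0, 0.3] and each
branch (0.3, 1].  Expression varies smoothly along every path: trunk
markers ramp from 30% effect at the origin to full effect at the
branch point and fade by mid-branch; branch markers ramp from 30%
effect at the branch point to full effect at the tip.  The meristem
anchor carries its own exclusive markers plus a weak (15% effect,
≈2-fold) progenitor trunk signature — meristematic cells are the state
upstream of the initials, and this adjacency is what lets the rooted
tree start at the meristem; the signature is deliberately below the
marker-detection fold-change gate so it cannot contaminate annotation.

One master seed drives deterministically derived per-stage child
streams, so identical configurations are bit-identical.

What the generator does *not* emulate: ambient RNA, doublets, batch
effects, bursty transcription, realistic gene-gene correlation beyond
the planted programmes, or dropout beyond what gamma-Poisson sampling
implies.  Passing recovery tests therefore demonstrates that the
implementation is faithful to its stated procedures under clean,
well-powered conditions — not that the procedures are robust to every
artefact of real droplet data.

## Problem sizes and numerical choices

The test suite and acceptance script run full-size atlases (1,050
cells × 2,000 genes) across 10–20 seeds; oracle-agreement checks use
10,000 random overlap columns, hundreds of random MST instances with
≤ 7 milestones (exhaustively enumerated via Prüfer sequences), and
random Fisher tables with universes ≤ 200.  Tolerances: 1e-12 for the
chi-squared arithmetic, 1e-10 for Fisher p-values, 1e-9 for Wilcoxon
p-values against the independent loop.  Degenerate inputs have defined
behaviour throughout: zero overlap columns are never significant,
zero-total cells are a normalization error, duplicate centroids are an
MST error, and an all-cells-removed QC outcome raises with the report
attached.

## Known limitations

- The annotation test treats overlaps as independent counts; it
  inherits the original method's assumption and is not a calibrated
  test of marker-set association (the `as_printed` variant especially).
- Cluster-boundary cells on a continuum make "majority type" a noisy
  target at coarse resolution; accuracy is therefore assessed at the
  pipeline default resolution.
- MSTs over noisy milestone centroids can mis-route when milestone
  granularity is much finer than the population structure; the
  pipeline's coarse-milestone default is a deliberate trade-off.
- The induced-gene test substitutes Welch's t for a count-model GLM
  and will lose power at very low replicate numbers or depths.
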