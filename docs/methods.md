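# Methods

`scdiversity` re-implements, as a tested library, a single-cell analysis of
intra-tumor transcriptional diversity in liver cancer: malignant cells are
identified from expression-inferred copy-number profiles, each tumor
receives a diversity score (the mean distance of its malignant cells to
their centroid in PC space), tumors are split into diversity-high and
diversity-low groups at the median, and ligand–receptor crosstalk between
fibroblast-like and malignant populations is scored against a
label-permutation null. A synthetic-data generator with full ground truth
drives all validation.

## Quality control and normalization

Genes are retained when detected (count > 0) in at least 3 cells of at
least one sample; requiring the rule per sample but retaining on "any
sample" avoids discarding tumor-private genes. Cells are retained when they
express at least 500 genes and at most 20% of their UMIs map to
mitochondrial genes (identified by the `MT-` prefix). Boundary readings are
strict: 500 genes and exactly 20% mitochondrial content both survive.
Retained cells are rescaled to 10,000 total counts and log(1 + x)
transformed; the pre-log scale is kept because the variable-gene window is
defined on it. The log transform is a config switch (`QCConfig.log_transform`)
since some analyses prefer the linear scale.

## Features

Highly variable genes satisfy mean normalized expression strictly inside
(0.05, 3) and normalized dispersion strictly above 0.5, where dispersion is
variance/mean of the pre-log normalized expression, z-scored within 20
equal-frequency bins of mean expression — the classical procedure these
threshold values come from. Selected genes are centered, scaled to unit
sample SD, and clipped at ±10. PCA is an exact full SVD (no randomized
solver), deterministic across platforms at these sizes, with the sign
convention that each component's largest-magnitude loading is positive.
t-SNE (scikit-learn, fixed seed) is provided for visualization only and
never feeds a score. The default PC count is 20; it is config-exposed
because reasonable analyses of the same data have used nearby values
(e.g. 23).

## Cell-type annotation

Cells are clustered with Leiden community detection on a Jaccard-weighted
shared-nearest-neighbor graph built in PC space (k = 15 neighbors, edges
pruned below Jaccard 1/15) — the clustering algorithm is a design choice;
any method yielding coherent clusters works, and resolution is
config-exposed. Each cluster's type score for a lineage is the mean
(over that lineage's markers present in the matrix) of the cluster-mean
z-scored expression; the arg-max lineage is assigned when its score is
positive (markers above the population average), otherwise the cluster is
"unassigned". Ties break lexicographically. The bundled panel covers
T cells, B cells, tumor endothelium (TEC), cancer-associated fibroblasts
(CAF), tumor-associated macrophages (TAM), and HPC-like cells; malignant
cells carry no lineage program and are expected to remain unassigned at
this stage — the CNV call, not the marker label, decides malignancy
downstream.

## CNV inference and the malignancy classifier

Expression enters on the scale conventional for this classifier family,
log2(x + 1) of counts rescaled to 1e5 per cell (equivalently TPM/10): the
0.05 signal threshold is calibrated in these units, and on the log(1 + x)
counts-per-10k scale the same dosage change produces roughly half the
footprint, leaving that cutoff unreachable. Cells annotated as
endothelium, fibroblast, or macrophage form the reference. Per gene the
reference mean is subtracted, residuals are clipped at ±3, and a centered
moving average over 101 genes (shrinking symmetrically near chromosome
ends) is applied within each chromosome in genomic order; rows are then
median-centered per cell, and the reference mean is removed once more so
reference cells average exactly zero. Mitochondrial contigs and
chromosomes with fewer than 3 annotated genes are excluded.

Two summaries classify cells. CNV *signal* is the mean of squared CNV
values across the genome. CNV *correlation* is the Pearson correlation of
a cell's profile with its sample's consensus — the per-gene mean over the
top 5% of cells by signal (at least one cell); a cell inside the top set is
compared against the consensus computed without it whenever the set has at
least two members, so no cell certifies itself. The consensus construction
is a documented convention of this package: the two scores and their
thresholds are standard, but the correlate's construction varies between
implementations. A cell is
malignant iff signal > 0.05 AND correlation > 0.5, both strict. On
simulated data the noise floor of the signal can exceed 0.05 for shallow
cells; the conjunction with the correlation term is what preserves
precision, which mirrors how the classifier behaves on real data.

## Diversity score

For each tumor with more than 20 malignant cells (strictly; smaller samples
are scored but excluded from grouping), the malignant cells' log-normalized
expression profiles — deliberately not re-restricted to variable genes nor
z-scaled, since global z-scaling normalizes away exactly the between-tumor
spread differences the score measures — are projected by per-sample PCA
onto the smallest set of leading components reaching 80% cumulative
variance (config `variance_kept`). The score is the mean Euclidean
distance to the arithmetic-mean centroid after one pass of outlier
exclusion: cells whose distance lies outside mean ± 3 sample-SD are
dropped and the centroid and score recomputed once. With the sample SD,
Samuelson's inequality caps |d − mean|/SD at (n − 1)/√n, so no cell can be
flagged when n ≤ 10 — documented small-sample behavior. Tumors at or above
the median score are "diversity-high", the rest "diversity-low"; an
all-equal degenerate case goes entirely to "high" with a warning. The same
machinery applied to CNV-profile rows yields the CNV-based twin score.

## Differential expression and signatures

Tumor cells from diversity-high vs diversity-low tumors are compared per
gene with a two-sided Wilcoxon rank-sum test (asymptotic, BH-adjusted);
the log fold change is the natural log ratio of group means of normalized
expression with a pseudocount of 1. Gene-set scores (e.g. the bundled
stemness panel: ICAM1, SOX4, ALDH1A1, BMI1, SOX9, SMAD2, MYC, and the
progenitor markers) are the per-cell mean of expression z-scored across
cells — a transparent stand-in for heavier gene-set variation machinery,
adequate for rank comparisons between groups.

## Ligand–receptor crosstalk

For a pair (L, R) between a sender and receiver type, the statistic is
½(mean L over sender cells + mean R over receiver cells), tested only when
L is detected in more than 10% of senders and R in more than 10% of
receivers. The null shuffles cell-type labels over all cells (the same
shuffles serve every pair, giving common random numbers for fold
comparisons); the one-sided p-value is (1 + #{null ≥ observed})/(1 + B)
with B = 1000 by default, BH-adjusted across all tested triples. The gate,
statistic and null follow the convention of the standard tool for this
analysis; the test is enrichment-only by design. The bundled pair table
holds the collagen/fibronectin–integrin candidates
(COL1A1/2–ITGA2/V, COL4A1/2–ITGA2, COL6A1/2–ITGA2, FN1–ITGA2/V).

## Synthetic data

The generator emulates a multi-sample 10x-convention cohort:

- **Counts** — negative binomial with gene-level base means drawn from a
  log-normal around `baseline_mean` (default 8, a deeply sequenced cohort
  of roughly 50–60k UMIs per cell; depth is what makes subtle subclonal
  divergence identifiable at the simulated sample counts), shared dispersion
  `nb_dispersion` = 0.2, and per-cell log-normal library factors
  (σ = 0.25).
- **Genome** — 20 chromosomes × 300 genes plus 13 `MT-` genes on `chrM`,
  which never intersects a CNV segment, so the mitochondrial QC filter is
  exercised independently. Marker, ligand/receptor and stemness gene names
  occupy the head of the last autosome, outside the default CNV segments.
- **Cell types** — each type elevates its canonical markers
  `marker_fold`-fold (default 4) and additionally carries a broad lineage
  program (100 random generic genes, fold 3): real lineages differ in
  broad programs, and without one graph clustering cannot resolve types
  that differ in only a handful of markers.
- **CNV** — malignant cells multiply NB means by the planted dosage;
  defaults put a quarter of the autosomal genome at 1.5×/0.5× (three
  gained and two lost whole chromosomes). Optional subclone-private
  segments create genetic subclones for the CNV-diversity twin.
- **Subclonal divergence** — one fixed program panel (10% of autosomal
  genes, drawn from the expressed upper half of base expression, because
  perturbing near-silent genes has no expression footprint); each
  (sample, subclone) applies i.i.d. Normal(0, σ_d) log-fold offsets on the
  panel. σ_d may be set per sample, which is how mixed-divergence cohorts
  for recovery experiments are built inside one shared feature space.
  Default 4 subclones per tumor.
- **Mitochondria** — mito gene means are rescaled per cell group so the
  expected mitochondrial UMI share equals `mito_fraction_target`
  (default 5%).
- **Crosstalk** — planted pairs multiply the ligand mean in the sender
  type and the receptor mean in the receiver type (default COL1A1–ITGA2,
  CAF → malignant, fold 4).

What the generator does *not* emulate: doublets, ambient RNA, batch
effects, UMI-level sequencing error, dropout beyond NB sampling, and
realistic co-expression structure within programs (offsets are
independent across genes). Passing recovery tests therefore demonstrates
the pipeline's correctness under its own model assumptions, not robustness
to those artifacts.

A companion fixture (`simulate_qc_fixture`) plants exactly countable QC
violations — cells expressing 499 genes, cells at 40% mitochondrial
content, genes detected in exactly 2 cells — with disjoint violation sets,
so filter counts can be checked for exact equality.

## Validation experiment sizes

The bundled validation suites use desk-scale designs chosen once: 600
cells (200 malignant / 200 reference / 200 other) for malignancy recovery;
16 tumors (4 per divergence level, 300 malignant cells each) for monotone
recovery of σ_d ∈ {0, 0.25, 0.5, 1}; 10 tumors (5 at σ_d = 0, 5 at
σ_d = 1) for median-split recovery; 200 distinct-gene null triples at
1000 permutations (in 5 independently permuted batches, which keeps the
type-I-error estimate near its binomial precision) for crosstalk
calibration.

## Numerical choices and edge cases

- SDs use ddof = 1 throughout scaling, z-scores and the outlier rule.
- Zero-variance genes are dropped from scaling with a warning;
  zero-variance CNV rows get correlation 0 with a warning.
- A zero-total cell is an invalid-state error in normalization (QC must
  run first).
- Moving-average windows must be odd; windows wider than a chromosome
  shrink symmetrically rather than erroring.
- The median split sends ties to "high" (arbitrary but fixed).
- Permutation p-values are lower-bounded at 1/(B + 1); p = 1 is attainable
  and exact for permutation-invariant data.
- All pipeline randomness (t-SNE, clustering, permutations) derives from
  one config seed; reruns are byte-identical.

## Known limitations

Per-sample PCA means scores from different cohorts are comparable only
through the shared feature space (same genes, same normalization); the
diversity score inherits a dependence on sequencing depth through the
noise floor of per-cell distances, so cross-dataset comparisons require
comparable depth. The annotation step assigns one type per cluster, so a
cluster mixing two lineages is labeled with the stronger one. The
crosstalk test treats single genes, not receptor complexes.
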