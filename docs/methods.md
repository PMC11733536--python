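# Methods

This note documents the models and procedures implemented in `lineagemap`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions adopted where the underlying
analysis left them open.

## Normalization and cluster profiles (`sc_core`)

Counts are library-size normalized to a fixed total per cell (default
10,000) and transformed with `log(1 + x)` (natural log, pseudocount 1 — the
common single-cell convention; base and pseudocount are configurable since
only "log-normalized" is specified by the analyses this package supports).
Cells with zero totals are left as zero columns and logged. Cluster profiles
carry two summaries per gene: the mean of log-normalized expression and the
detection rate (fraction of cells with raw count > 0). Clusters with fewer
than 20 cells (configurable) are dropped from profiles; the weighted mean of
cluster means over the retained cells equals the global mean, which the test
suite asserts to 1e-9 relative tolerance.

Cell-cycle scoring follows the binned-control convention: all genes are
binned into 24 equal-frequency bins of mean expression, 100 control genes
are sampled (without replacement, seeded) from every bin containing a phase
gene, and a cell's score is the mean expression of the phase genes minus the
mean of the controls. Equal-frequency (quantile) binning was chosen because
"bins by expression level" behave poorly as equal-width bins on the heavily
right-skewed mean-expression distribution; this is the one genuinely open
choice in the procedure and is isolated behind `CellCycleParams`.

## Synthetic data (`synthetic`)

The generator emulates the structure the analyses assume, not a real
transcriptome:

- a 2,000-gene genome over 20 ordered chromosomes (100 genes each, 10 kb
  spacing), so windowed CNV scoring and interval algebra are exercisable;
- five lineage classes (MGE, CGE/LGE, excitatory, glia, immune) whose
  identity is encoded twice, mirroring the two fingerprint features: the
  panel TF's negative-binomial mean and its detection probability. The
  class/TF table follows telencephalic patterning logic (FOXG1
  pan-telencephalic, NKX2-1/LHX6 MGE, GSX2 ventral LGE/CGE, DLX1/2/5/6 all
  GABAergic, PAX6/EMX1/EMX2/TBR1/EOMES dorsal);
- 120 additional marker genes per class (8-fold boost) over a shared
  lognormal background (median 0.5 counts), giving realistic UMI totals of
  roughly 1.5-2k per cell and supporting full-length (75-100 gene)
  signature derivation;
- negative-binomial counts (dispersion 0.1) with Bernoulli dropout
  (retention 0.9), cluster-level lognormal jitter (σ = 0.25) on panel-TF
  means so clusters within a class are distinct.

Class structure (marker identity, background means) is a function of
`spec.seed` alone; the sampling seed only drives cell realisations, so a
reference/query pair shares its populations. Pseudobulk samples are sums of
simulated cells drawn from named class mixtures. The CNV fixture uses
lognormal base means around 8 counts (dispersion 0.05) so the whole genome
clears the 0.1 expression cutoff — a trisomy-like 2× gain across three full
chromosomes (a 300-gene block) at a chosen malignant fraction. Peak fixtures
place identical true intervals in both CUT&RUN replicates (padded in ATAC)
and decoys that each violate exactly one filter rule.

Not emulated: transcriptome-wide co-expression, batch effects, ambient RNA,
doublets, continuous differentiation trajectories, and subclonal CNV
structure. Tests passing on this generator therefore demonstrate the
*procedures* are implemented correctly and recover planted structure; they
do not certify performance on real tissue.

## TF fingerprint classification (`fingerprint`)

Features: per TF and cluster, (1) mean log-normalized expression min-max
scaled to [0, 1] per TF *within each dataset* (datasets need not share
expression ranges; constant columns map to 0 to avoid 0/0), and (2) the raw
detection rate. Classifier: one-vs-rest `LinearSVC`, hyperparameters
(C ∈ {0.01, 0.1, 1, 10}; hinge vs squared-hinge) selected by inner
stratified cross-validated accuracy. Evaluation: k = 4 folds built per class
by seeded shuffle + round-robin, so classes stay balanced across folds;
precision and recall are computed across held-out clusters within each
class. `CVReport` exposes both the median-across-folds per-class aggregation
and the pooled mean, since either reading of "median across folds" is
defensible.

## ssGSEA (`enrichment`)

The score is the *sum* of the running difference between the rank-weighted
in-set ECDF (weights `r^α`, α = 0.75) and the unweighted out-of-set ECDF —
the statistic of the GSVA ssgsea lineage with `norm = FALSE` — not the
maximum deviation; the max-deviation variant is available via
`SSGSEAParams(statistic="max")`. This is the single most consequential
interpretation in the module and is pinned by an exhaustive brute-force
double-ECDF oracle in the tests (all 62 non-trivial subsets of a 6-gene
universe, three α values, 1e-10 tolerance). Ties default to ordinal-by-input
order (deterministic); average ranks are available. Range normalization,
when requested, divides by the global score range across the matrix.
Differential enrichment uses Welch t-tests (the unequal-variance choice is
ours; only "t tests" is specified) with BH adjustment; missing scores are
excluded pairwise, never imputed.

## Signatures (`signatures`)

Markers are one-vs-rest Wilcoxon rank-sum tests (normal approximation with
tie correction, vectorized); genes enter a signature if BH-adjusted p < 0.05
with positive average log2 FC (computed as the difference of mean
log-normalized values converted to log2 — the convention of the major
single-cell toolkits), sorted by log2 FC, ribosomal (RPS/RPL/MRPS/MRPL
substrings) and mitochondrial ("MT-" prefix; mouse casing variants when
`species="mouse"`) symbols removed, truncated at 100, dropped below 75.

The discriminance filter counts, per background sample, membership in the
top 10 signatures by score; among the A signatures appearing at least once,
`ceil(0.10 · A)` are excluded, extended to all signatures tied with the last
excluded count. The ceil-plus-tie-extension rule is consistent with an
observed exclusion of 15 at A = 135 ("including 1 tie"); both the decile and
the tie policy are arguments. Zero-appearance signatures are never excluded.

Ortholog maps keep only strict 1-to-1 pairs (any source or target occurring
twice in the raw table discards all its pairs). Signatures may fall below 75
genes *after* mapping and are retained with a warning — the length floor
applies at derivation.

Tumor-type signatures intersect, across all pairwise comparisons, genes with
adjusted p < 0.05, base mean > 100 and log2 FC > 1 *in favor of the target
group* (one-sided, since signatures mark identity), ranked by mean Wald
statistic. The DE tables are inputs; the bundled `simple_wald_de` (normal
theory on log2 counts) exists to exercise the machinery on synthetic bulk
data and is explicitly not a negative-binomial GLM.

## Consensus annotation (`consensus`)

References are filtered (≥100 cells per type) and subsampled (≤500,
seeded), and all predictors train on genes detected in both reference and
query. Built-ins: argmax Spearman correlation against type-mean profiles
(average ranks for ties; tie-broken by reference order, logged; constant
cells are "unassigned") and a per-cell linear SVM. The vote first aggregates
fine labels through the ontology, then assigns the unique plurality label
with support ≥ 2; plurality ties or maximum support 1 give "no consensus".
"Unassigned" is excluded from the counts and is distinct from "no
consensus". Whether {A, A, B, C} should require a strict majority instead is
ambiguous in threshold-vote schemes; plurality-with-≥2 is the default and
`strict_majority=True` switches the rule. Two-step annotation re-runs cells
whose first-pass consensus is categorized "neuron" against the adult
reference; second-pass labels landing outside the neuron category (labels
discrepant between references) become "no consensus".

## CNV inference (`cnv`)

The scorer implements the documented core of inferCNV-style profiling
without its Bayesian denoising or HMM: per-cell totals scaled to the median
library size (keeping values on the count scale, so the +1 pseudocount does
not compress moderate-expression fold changes), `log2(1 + x)`, per-gene
centering on the reference-cell mean, clamping at ±3, windowed smoothing
(101 genes) within chromosomes, per-cell median recentering (absorbing the
library-size shift a large gain induces in all other genes), and per-window
reference-median subtraction. Genes below the 0.1 mean-expression cutoff and
genes failing the annotation rules (human: MT-/MRPS/MRPL/RPS/RPL/HLA-;
mouse: mt-/Mrps/Mrpl/Rps/Rpl/H2-/H60 and non-1–19/X/Y chromosomes) are
excluded and reported.

Smoothing is mass-conserving: each gene's centered value is spread uniformly
over the windows containing it, which equals a centered moving average in
the interior and conserves the per-cell mean within each chromosome exactly
(plain truncated-window averaging does not). Windows shrink (with a log
message) on chromosomes shorter than the window.

Malignant calling cuts a Ward hierarchy (Euclidean distance; the linkage is
our choice, only "hierarchical clustering" being specified) into subtrees
(default 8) and labels a subtree malignant when its mean per-window |score|
exceeds `sd_amplifier` (1.75) times the reference-cell score SD. Joint
clusters spanning multiple samples with more than 5 % initially-normal
members flip to normal wholesale. Normal-reference refinement clusters cells
(PCA, 20 components; Leiden at resolution 0.2 via scanpy), re-clusters each
cluster excluding immune cells (resolution 0.2, seed 100), discards
subclusters under 10 cells, and admits subclusters whose target-gene
(Foxr2) expression is *not* significantly higher than in immune cells
(one-sided Wilcoxon, p ≥ 0.05); an optional self-referential CNV pass
removes candidate cells sitting in CNV-bearing subtrees. The refinement is a
single pass; iterating to convergence is possible but not done, since the
procedure it follows is described as one pass.

## Peak refinement (`peaks`)

All intervals are BED half-open. Overlap between `[s1, e1)` and `[s2, e2)`
is `max(0, min(e1, e2) − max(s1, s2))`; a CUT&RUN peak is removed when this
reaches 10 bp against any control peak (9 bp survives). All threshold
comparisons remove the boundary ("equal or lower/longer"): −log10 q ≤ 6,
signal ≤ 6, length ≥ 10,000 (ATAC: q ≤ 4, signal ≤ 2, plus standard
chromosomes and any-overlap blacklist removal). A missing q-value (−1
sentinel) fails the q filter and is logged. The consensus is the
base-pair-level triple intersection of the two *filtered* replicates and the
filtered ATAC set, emitted as maximal runs; the filters are order-independent
and every removal is attributed to exactly one named rule. Motif windows are
`[center − 100, center + 100)` with `center = floor((start + end)/2)`,
clipped at zero. Motif discovery itself is out of scope.

## Problem sizes and tolerances

Tests and the acceptance script run at desk scale by design: the fingerprint
experiment uses 3 classes × 25 clusters (~4,000 cells × 2,000 genes), CNV
recovery uses 400 cells, the vote and ssGSEA checks are exhaustive over
small universes, and randomized property checks use 100–200 trials. Numeric
tolerances: 1e-10 against the ssGSEA oracle (pure floating-point
re-expression), 1e-9 relative for profile-mean conservation, 0.2 log2 for
CNV block recovery (shot noise plus Jensen-gap bias of log-scale counts),
and binomial 99 % bounds for t-test calibration. Degenerate inputs
(all-zero cells, constant feature columns, short chromosomes, empty peak
sets) are handled and tested explicitly rather than rejected.

## Known limitations

- The CNV scorer is a transparent stand-in validated by ground-truth
  recovery; it is not numerically comparable to inferCNV output.
- `simple_wald_de` understates dispersion for real RNA-seq counts; use real
  DE tables for anything beyond synthetic exercises.
- The correlation/SVM predictors are two of the four methods used in
  full-scale consensus workflows; external predictors must be supplied as
  label tables (or via the predictor interface) to reproduce a 4-method
  vote.
- Signature derivation assumes gene symbols follow human or mouse
  conventions for the housekeeping filters; other nomenclatures pass
  through unfiltered.
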