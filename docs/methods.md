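# Methods

`invadome` implements a regional differential proteomics analysis for
laser-microdissected patient-derived xenografts, where tumor material and
host stroma are distinguished by species of origin: human proteins report
on the tumor, mouse proteins on the mouse brain stroma. Two regions are
compared — the angiogenic tumor core (condition `A`) and the invasive rim
(condition `I`) — across three biological samples with three technical
replicates each, i.e. nine replicate columns per condition.

## Data model

A quantification table holds strictly positive label-free abundances for
proteins × replicate columns, with explicit missingness (empty cell or
`NA`; zeros are rejected so that absence is never conflated with a measured
zero). Columns are named `<condition>_s<sample>_r<replicate>`. Human and
mouse proteins travel in one table with a species column and are analyzed
as parallel datasets.

## Reproducibility filter

For every (protein, condition, sample) triplet the coefficient of
variation CV = σ/μ of the technical replicates measures quantification
dispersion; σ is the sample standard deviation (n−1 denominator, the
default dispersion estimate at n = 3; a `ddof` switch gives the population
form). A protein is retained only if every defined CV is below the
threshold (default 0.8) in both conditions. Triplets with fewer than two
present values contribute no CV and do not veto retention — punishing
absence is the presence filter's job, and conflating the two gates would
make the CV filter's behavior depend on the missingness mechanism. CV
histograms are emitted as binned count tables (bin width 0.05) so the
threshold choice can be inspected numerically.

The presence (aggregation) gate then keeps proteins quantified in ≥ 6 of
the 9 columns of *each* condition, and flags the "common" subset present
in every column; downstream sample-level clustering uses the common
subset.

The CV filter runs on raw abundances, before normalization: CV is
scale-invariant per column set, and the filter precedes normalization in
the stage order.

## Normalization and imputation

Median-ratio normalization: the reference profile is the per-protein
median across all columns (present values only); each column is scaled by
the inverse of the median of its ratios to that reference, so afterwards
every column's median ratio to the reference is 1. The procedure is
idempotent.

Missing cells are imputed at the per-column 1st percentile of present
values — the standard low-abundance imputation for left-censored LFQ
missingness. Imputation feeds only clustering and the clustermap; the
differential test always runs on observed values, because imputing before
a t-test fabricates degrees of freedom.

## Differential expression

Per protein, Welch's unequal-variance t-test compares the invasive and
core replicate vectors (observed values only, ≥ 2 per group required;
otherwise the protein is excluded from correction). P-values are
two-sided: direction is claimed post hoc in both directions, so a
one-tailed test would be anti-conservative. Benjamini–Hochberg step-up
adjustment controls the FDR across proteins. Effect size is
log2FC = log2(μ_I/μ_A) over present values; log base 2 is used uniformly.

Three nested hit tiers (nesting holds by construction for human data):

| tier | rule | default |
|---|---|---|
| `significant` | padj below threshold | padj < 0.01 |
| `enrichment_hit` | + \|log2FC\| gate for ORA | > 1 |
| `clustermap_hit` | + species \|log2FC\| gate | > 2 human, > 5 mouse |

The mouse clustermap gate is higher because stromal fold changes between
regions run much larger than tumor-intrinsic ones. A documented no-op hook
(`missing_value_variant_hook`) marks the extension point for an upstream
missing-value inference variant whose exact rule is under-specified.

## Clustering and bootstrap support

Hierarchical clustering uses Euclidean distance with the Ward-D2
criterion (scipy's `ward`, equivalent to R `hclust` ward.D2 on Euclidean
distances; merge ties break deterministically by lowest index). Sample
dendrograms cluster the 18 replicate columns of the common subset on log2
ratios to the reference profile, without row scaling; the protein
clustermap z-scores each protein row of the log2 matrix first.

Branch support: features are resampled with replacement `bootstrap_n`
times (default 200) and the bootstrap probability (BP) of each internal
node is the percentage of resampled trees reproducing exactly its member
set. An approximately-unbiased (AU) estimate via multiscale bootstrap
(resample sizes 0.5–1.4× the feature count, normal-quantile regression
z(s) = v√s + c/√s, AU = 1 − Φ(v − c), with saturated-BP nodes reported at
the 0/100 limits) is implemented but experimental and off by default: BP
is the load-bearing statistic, and the AU fit is unstable exactly where BP
is already decisive.

## Over-representation analysis

The enrichment-tier subset is tested against GMT gene-set collections
with the hypergeometric upper tail (probability of at least the observed
overlap when drawing the query from the universe), BH-corrected across
sets, enriched at adjusted p < 0.05. The universe is the aggregated
(detected) proteome of the species analyzed, not the genome: only
detectable proteins could have entered the query, and a genome background
would inflate every enrichment. The `ratio` column (overlap / query size)
is the usual dot-size statistic. Ranked-list methods with a permutation
null are out of scope — the input here is a thresholded subset, which is
exactly the ORA setting.

## Interaction network and MCL

Edge lists are STRING-style (node, node, confidence); scores above 1 are
auto-interpreted as the 0–1000 integer scale. Tiers: medium ≥ 0.4, high
≥ 0.7, highest ≥ 0.9. Edges below the minimum confidence (default 0.4;
boundary values are kept) are dropped, then proteins left without any
interaction are removed.

The Markov Cluster Algorithm is implemented from scratch: the
confidence-weighted adjacency matrix gets self-loops (weight = each node's
maximum incident confidence, the standard regularization against parity
oscillation), is column-normalized, and then alternates expansion (matrix
squaring) with inflation (elementwise power, default 2.0, followed by
column renormalization), pruning entries below 1e−5, until the maximum
elementwise change falls below 1e−8 (warning and best-effort readout at
200 iterations otherwise). Clusters are attractor systems of the limit
matrix; each node joins the system receiving most of its flow, ties going
to the lexicographically smallest seed, so every node gets exactly one
label. Intra- vs inter-cluster edges are flagged in the edge table.
Inflation controls granularity and is exposed in the config; higher
inflation gives finer partitions on the fixtures, but this monotonicity is
a heuristic, not a theorem.

## AngioScore

Per gene, the AngioScore is the percentage of its publication abstracts
containing at least one angiogenesis keyword — case-insensitive,
whole-word/whole-phrase matching, no stemming, for determinism and
auditability. The lexicon is an editable one-keyword-per-line file; the
default list covers angiogenesis/angiogenic/neovascularization-style
terms. Scores depend on the lexicon and the corpus snapshot, so absolute
values are not comparable across corpora; the meaningful output is the
core-vs-invasive contrast. The group comparison takes the top-30 hits per
area (ranked by |log2FC| among significant proteins — the ranking rule is
a package choice and configurable), averages scores, reports the
core/invasive ratio and a two-sample t-test, and lists the 20 highest
scores per area. Genes without publications are excluded from group
statistics. No live literature querying: the corpus is an offline
directory of per-gene abstract files.

## Synthetic data generator

The generator is first-class, tested code defining the study conditions.
Per protein: base log2 abundance ~ N(20, 2) (typical LFQ intensity
scale); biological-sample effects ~ N(0, 0.25) in log2, drawn per
(protein, sample); the condition effect equals the planted log2FC, applied
to condition I; technical replicates are multiplicative log-normal noise
centered so the linear-space mean is preserved, with log-sd
σ = √ln(1 + CV²). The technical CV follows a two-point mixture: bulk 0.2,
with a 10% heavy tail at 1.2 — the irreproducible minority the 0.8 gate
exists to remove. A planted fraction (default 20%) of proteins is
differentially expressed with |log2FC| ~ U(1, 6), 25% invasive-up
(regional studies of this design find core-up dominance). Missingness is
logistic in log2 abundance (midpoint 16, steepness 1 → ~50% dropout at
abundance 2¹⁶, ~2% at 2²⁰), making low-abundance proteins drop out more —
the mechanism presence filters exist for. Defaults are 750 human and 520
mouse proteins on the full 2 × 3 × 3 grid.

The corpus generator gives every gene a fixed number of synthetic
abstracts; abstracts of core-area genes mention a lexicon keyword with
probability 0.3, all others 0.2, so the expected group score ratio is 1.5.

Not emulated: peptide-level quantification and shared-peptide inference,
batch effects beyond the sample term, correlated missingness, real
abstract language. Passing tests therefore demonstrate correctness of the
pipeline's statistics and bookkeeping under a known generative model, not
robustness to every pathology of real LFQ data.

## Numerical and reproducibility choices

- Tables are written with 6 significant digits, `NA` for missing; two
  writes of the same object are byte-identical, and a fixed seed makes the
  whole pipeline bytewise reproducible.
- Welch on two identical constant groups returns t = 0, p = 1 (no
  evidence) rather than NaN.
- BH excludes undefined p-values and restores input order; adjusted
  values are capped at 1.
- Degenerate inputs error early with the offending item named (duplicate
  accessions, malformed headers, non-positive abundances, all-missing
  columns, grid mismatches).

## Problem sizes used in the checks

The verification experiments run at deliberately modest scale, chosen to
make sampling noise negligible relative to the asserted margins: oracle
equivalence on 1000 random instances per primitive; FDR control on 20
null simulations of 700 proteins; effect recovery on 700 proteins with
planted |log2FC| ∈ [2, 6] at bulk CV 0.2 (full 9-vs-9); filter recovery on
600 proteins with a 20% CV tail; MCL on 50 planted-partition graphs of
3 × 10 nodes; bootstrap support on 8 × 30 matrices at 200 resamples;
AngioScore on 30 genes per group at 200 abstracts per gene.

## Known limitations

- The t-test treats the 9 replicates per condition as independent,
  although technical replicates share a biological sample; with the
  default sample effect (sd 0.25 log2) this mildly understates the
  variance of the fold-change estimate. A mixed or sample-averaged model
  is a possible extension.
- No moderated (empirical-Bayes) variance estimation; at n = 3 triplets
  per condition the plain Welch test is noisier than limma-style
  moderation would be.
- AU support is experimental; its multiscale fit is unreliable for nodes
  whose BP saturates.
- ORA ignores gene-set ancestry/redundancy; overlapping sets are tested
  independently.
- MCL granularity depends on inflation, which has no data-driven default
  here (2.0 is the canonical choice).
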