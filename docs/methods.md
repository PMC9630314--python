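# Methods

This note documents the models, numerical conventions and design choices
behind `coexnet`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Cross-cohort normalisation

Cohorts arrive in FPKM, TPM or RSEM estimated transcript fraction.
FPKM → TPM divides each sample by its column sum and multiplies by 10⁶
(valid without gene lengths because, within a sample, FPKM and TPM differ
only by a constant); transcript fractions are multiplied by 10⁶. Merging
restricts rows to the exact, case-sensitive intersection of gene symbols
(sorted for determinism — no alias resolution, which would make the merge
dependent on an annotation snapshot), concatenates samples, and rescales
every sample to a 10⁶ total. This last rescale defines **pseudo-TPM**: the
row subsetting removes mass, and redistributing it is the only reading
under which post-merge columns can sum to 10⁶. Samples with an all-zero
column are hard errors, never silently dropped (dropping would change n).
Per-cohort gene summaries report median, quartiles and a 95% CI of the
median from a seeded percentile bootstrap (2,000 resamples); the bootstrap
method is a package choice, made explicit because plotted CIs rarely state
one.

All conversions and the merge preserve within-sample rank order; rescaling
an already-rescaled matrix is a no-op; cohort order only permutes columns.
These invariants are tested.

## Gene-network similarity (second-order correlation)

A gene's *network* is its vector of correlations to all other genes.
First-order correlations default to Pearson on log₂(x + 1): TPM-scale data
are strongly right-skewed and a handful of extreme samples would otherwise
dominate every profile. Method (Pearson/Spearman) and transform
(log2p1/none) are configurable and recorded on the result.

The similarity of genes i and j is the Pearson correlation of rows i and j
of the first-order matrix with positions i and j deleted from both
vectors. The exclusion matters: the structural 1 at each gene's own
diagonal position (and the pair's mutual correlation appearing in both
rows) would otherwise inflate every pairwise similarity. The whole matrix
is computed in closed form from row sums, row sums of squares and one Gram
product, and is validated against an explicit double-loop re-derivation to
10⁻¹⁰ on every fixture up to 30 genes. Zero-variance genes have undefined
correlations; they are excluded with a logged count, never imputed.
Degenerate profile pairs (zero variance after exclusion) are recorded as
missing. Results are clipped to [−1, 1], symmetrised against rounding, and
carry a unit diagonal by construction.

A **network signature** is every gene whose similarity to the query meets
a threshold (default 0.7), sorted by score descending with lexicographic
tie-break; the query belongs to its own signature (self-similarity is 1).
Signature *distributions* — one test gene's similarities to all signature
members — are the quantitative form of the violin-plot comparison; set
overlap between signatures is quantified with Jaccard and overlap
coefficients, an added quantification of what the violins show visually.

Embedding uses UMAP (umap-learn) on the rows of the similarity matrix,
n_neighbors = 15, min_dist = 0.1, Euclidean metric, fixed seed 42 by
default; all parameters are recorded in the output. With a fixed seed
umap-learn is single-threaded and reproducible.

## Preranked GSEA

The association profile ranks genes by their correlation with a query
gene, computed per cohort and averaged across cohorts (arithmetic mean),
descending, ties broken lexicographically for determinism. An alternative
`profile_mode="mean_expression"` ranks by mean transformed expression
instead — both constructions are exposed because either reading is
defensible for a profile "averaged across datasets"; neither is asserted
as canonical.

The enrichment score is the weighted Kolmogorov–Smirnov statistic: hits
increment the running sum by |score|^p normalised to the set's total
weight (p = 1 by default), misses decrement by 1/(N − N_h); ES is the
maximum-magnitude deviation. When the positive and negative extrema tie in
magnitude (exact ties occur with rational scores), the positive deviation
is reported — the same convention in the reference path, the O(k)
permutation kernel, and the test oracle, so they agree to 10⁻¹².  Note
that with p > 0, promoting a hit up the ranking can *decrease* a positive
ES (the promoted hit's larger weight dilutes the others); the familiar
monotonicity property holds only at p = 0 and is tested there.

The null is a gene-label permutation: for each set, 1,000 (configurable,
minimum 100) random same-size subsets of the profile universe, drawn
independently per set. NES divides ES by the mean magnitude of the set's
same-sign null ES; nominal p is the same-sign null tail fraction (no
add-one smoothing, so p = 0 can occur at finite permutations); FDR q is
the GSEA convention — the pooled null NES tail fraction divided by the
observed NES tail fraction, clipped to [0, 1]. Sets with no overlap with
the profile are skipped with a logged warning. Filtering defaults to
|NES| ≥ 1.4 and q ≤ 0.05, the cutoffs used when tabulating significant
oncogenic-signature enrichments.

## Single-cell positivity

A cell is positive for a marker when its raw count passes a detection
floor; the default floor is count > 0 ("detection of the transcript"), a
higher floor is available for sensitivity analyses since published
analyses rarely state one. Fractions are exact integer tallies per
condition; the only floating step is the final division, reported both as
a fraction and as a percentage rounded to one decimal. No normalisation,
clustering or tumor-cell inference happens here — inputs are assumed to be
cells already identified upstream.

## Association statistics

Pearson r (two-sided p via t = r·√((n−2)/(1−r²))), one-way ANOVA, pooled
and Welch t-tests, Fisher's exact test (two-sided p as the sum of
hypergeometric probabilities ≤ the observed table's — the definition that
matches full enumeration exactly; sample odds ratio a·d/(b·c)) and the 2×2
chi-square with optional Yates correction. Computation delegates to
scipy.stats behind this validated surface; tests compare every statistic
against independent enumeration or closed-form oracles. High/low
dichotomisation of a continuous marker defaults to a median split, with
the quantile configurable and meant to be reported. A Benjamini–Hochberg
helper exists but is never applied implicitly.

## The synthetic benchmark

The generator plants known structure so recovery can be asserted:

- **Modules**: a shared latent factor on the natural-log scale
  (z_g = √ρ·f + √(1−ρ)·ε_g), so every within-module pair has correlation
  exactly ρ on the log scale, then exponentiation gives right-skewed,
  heavy-tailed positive marginals. Marginal shape and target correlation
  are controlled independently — the reason for the copula over a direct
  multivariate-normal covariance. Module log-mean defaults to 4 (~55
  abundance units) with unit log-SD.
- **Background genes** are mutually independent (correlation exactly 0),
  log-normal with cohort-level `noise_sd` (default 1), keeping
  planted-module recovery tests sharp. `noise_sd` governs background
  spread only; module spread comes from the module spec so ρ is not
  diluted.
- **Units**: TPM columns are scaled to 10⁶; RSEM-fraction columns to 1;
  FPKM columns get a log-normal per-sample library factor (σ = 0.3), so
  the conversion paths see realistic inputs. Note that per-sample scaling
  (TPM/RSEM) is compositional: with very few genes it induces visible
  spurious correlation — a property of the unit, not the generator — so
  independence checks use FPKM or many genes.
- **Single-cell counts**: per gene, a cell is detected with the gene's
  detection fraction; detected counts are 1 + Poisson(mean − 1), making
  "detected ⇔ count > 0" unambiguous.
- **Gene sets**: one exact set per planted module plus uniform random
  decoy sets from the universe.

All generators are pure functions of spec + seed (bit-reproducible).

### Benchmark geometry

Desk-scale problem sizes, chosen once as representative study conditions:
signature-recovery and violin benchmarks use an 8-gene module at ρ = 0.9
among 72 background genes, 500 samples, 20 replicates; monotonicity of
recall is checked over ρ ∈ {0.5, 0.7, 0.9}. GSEA power uses the module
among 192 background genes (the larger universe mirrors, at desk scale,
the transcriptome-wide setting where null enrichment of a small set is
weak) with 30 decoy sets of 15 and 1,000 permutations; calibration uses a
structureless 500-gene universe, 200 random sets of 15 — sets drawn from
a small universe overlap heavily and their p-values correlate, so the
larger universe keeps the empirical type-I rate close to its nominal
binomial behaviour. Single-cell recovery uses 10,000 cells.

### What passing does and does not show

The generator reproduces the statistical structure the pipeline assumes —
planted correlation, heterogeneous units, zero-inflated counts — and
nothing else. It does not simulate copy number, tumor purity, batch
effects, library-preparation biases, or dependence between background
genes; passing these benchmarks shows the algorithms recover the structure
they target under their own assumptions, not that real-cohort conclusions
are insensitive to those confounders.

## Known limitations

- The similarity matrix is dense O(G²) memory; the implementation is
  designed to be correct at up to a few thousand genes, not to reproduce
  transcriptome-scale (~19k genes) memory behaviour.
- Permutation p-values have resolution 1/n_permutations and can be 0.
- Exact symbol matching means diverging annotations across cohorts shrink
  the merge intersection; no alias table is consulted.
- The FDR q follows the GSEA pooled-tail convention, which is known to be
  liberal for small collections.
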