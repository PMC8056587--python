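# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic corpora do and do not
emulate, and the numerical conventions that pin down edge cases.

## Sample cataloguing and filtering

Tissue assignment is positive-minus-negative regex matching on a lowercased,
whitespace-collapsed description. Patterns are tried against both the whole
string and each token, so `^pfc$`-style anchors act token-level while
`\bstriatum\b`-style boundaries work on the full text. A sample that
positively matches two or more tissue labels after vetoes is left
*unassigned* rather than resolved by any heuristic: ambiguity between curated
terms is a dictionary defect, and guessing would silently mislabel samples.
Disease status defaults to `normal` in the absence of cancer evidence, since
"normal" here means non-cancer, not certified-healthy.

The three filters run in a fixed priority — single-cell terms, then the read
floor, then group size — so each excluded sample carries a single
reproducible reason. Both thresholds read "fewer than" literally: a sample
with exactly 5,000,000 reads and a group of exactly 30 samples survive.
Group sizes are counted after the per-sample removals on (tissue, disease)
pairs; unassigned samples belong to no group and therefore cannot be
retained (their recorded reason is `small_group`, the group being empty).
Defaults: `min_reads = 5_000_000`, `min_group_size = 30`. Filtering is
idempotent.

Single-cell term matching is deliberately naive (`"single cell"` flags
"single cell suspension, bulk sequenced" too); the cost of a rare false
positive is far below the cost of letting sparse droplet data into a Pearson
correlation matrix.

## Normalisation and variance stabilisation

Size factors are the median, over reference genes, of each sample's counts
divided by the gene's geometric mean across samples. Genes with any zero
count are excluded from the reference (their geometric mean is 0); zeros are
still transformed downstream, the transform being finite at q = 0.

Per-gene dispersions are method-of-moments estimates on size-factor-
normalised counts, `α̂ = max(0, (s² − μ)/μ²)`, and the parametric trend
`α(μ) = a₀ + a₁/μ` is fitted by iteratively reweighted least squares with
gamma-family weights `1/fitted²` and non-negativity enforced at every step
(NNLS). Estimates outside `[1e-4, 10]` are excluded as outliers, and at
least 10 genes with normalised mean > 0.5 are required — guards that keep a
handful of degenerate genes from steering the two-parameter fit. On
numerical failure the fit falls back to a₀ = median positive dispersion,
a₁ = 0, with a warning. This is a deliberately lighter re-derivation than
empirical-Bayes dispersion shrinkage: the trend's two parameters are all the
closed-form transform needs, and on negative-binomial data with a planted
trend (2000 genes × 100 samples) both are recovered to within a few percent.

The transform itself is the antiderivative of `1/√v(μ)` for the trend's
variance function `v(μ) = μ(1 + a₁) + a₀μ²`,

    vst(q) = log2( (2a₀q + 1 + a₁ + 2√(a₀q(a₀q + 1 + a₁))) / (4a₀) ),

affinely rescaled so vst(q) → log2(q) as q → ∞. It is strictly increasing,
finite at zero, and agrees with direct numerical integration of `1/√v` to
machine precision. When the fitted a₀ is 0 (Poisson-like data) the log2
rescaling is undefined, so a₀ is floored at 1e-8; the transform is then
effectively log2-like from small q onward. The transform is *blind*
(design-free): the corpus has no design matrix, only post-hoc group labels.

## Correlation store

Pearson correlations (optionally Spearman) are computed per group on the VST
scale, stored as float32 matrices with genes in a fixed sorted order and the
group's sample count n. Zero-variance genes get NaN rows/columns and are
dropped before every ranking, enrichment, or variance computation — never
imputed. Per-coefficient significance uses the two-sided Student-t
convention, `t = r√(n−2)/√(1−r²)` on n−2 df, with |r| = 1 mapping to p = 0.
Correlations are computed on all genes rather than a per-group expressed
subset; the NaN mechanism already removes the genuinely uninformative ones,
and a per-group expression filter would make gene universes incomparable
across groups.

Consensus ranking across groups aggregates by the mean correlation
(median available via a flag): the mean rewards consistent co-expression and
is the natural default when no single group should dominate.

## corGSEA

Genes are ranked by signed correlation, descending, ties broken by symbol
for determinism; the query gene is removed first (its self-correlation of 1
would occupy the top rank as pure noise). The enrichment statistic is the
weighted Kolmogorov–Smirnov running sum: hits add `|r|ᵖ / Σ_hits |r|ᵖ`,
misses subtract `1/(N − N_hits)`, and ES is the extremum by absolute value.
The weight exponent defaults to p = 1 (the standard weighted statistic);
p = 0 reduces to the classic KS statistic and is invariant under monotone
score transforms. The running sum is accumulated as separate hit and miss
cumulative sums with one final division each, so the unweighted statistic is
exact; ties in |extremum| (which occur at rational crossings) resolve to the
earliest position.

The null is gene-label permutation: random same-size sets from the ranked
universe, `n_perm = 1000` by default, cached per set size within a run.
NES divides ES by the mean |null ES| of the same sign, sides normalised
separately (NES is missing if the null has no same-sign values). The
p-value is the one-sided upper tail of |ES| against the full null,
`p = (1 + #{|null| ≥ |ES|}) / (n_perm + 1)`: under the null |ES| is
exchangeable with the null draws, so p is uniform on its grid, it can never
be 0, its floor is 1/(n_perm + 1), and both enrichment directions are
detected symmetrically. A sign-conditional tail (normalising by only the
same-sign null count) was rejected because its attainable floor varies with
the null's sign split and its null distribution is only conditionally
uniform. Set-size bounds default to 15–500; out-of-bounds sets are recorded
as skipped, not errors. BH adjustment runs across all tested sets.

Over-representation analysis is the hypergeometric upper tail
`P[X ≥ overlap]` with population = gene universe, successes = set ∩
universe, draws = query size, BH-adjusted across sets. The same kernel
backs the top-K-correlates overlap benchmark.

## Analysis modes

*Gene vs gene* uses the two-point sample variance `(r₁ − r₂)²/2`
(n−1 denominator), symmetric in its arguments, on the intersected universe
with both query genes removed; the same metric on paired NES values ranks
diverging enrichments. In group mode with one gene, each tissue with both
conditions gets the correlation between the gene's two correlation profiles
plus a two-sided Wilcoxon rank-sum contrast of its VST expression,
star-coded at .05/.01/.001/.0001.

*Gene vs gene list* reports two readouts that answer slightly different
questions and are deliberately kept separate: the headline empirical p — the
tail probability of the observed mean correlation under the random-list null
— and the per-replicate Welch t-test p-values, whose density is the
traditional visual of this test. The secondary list is sorted internally so
the result is invariant to input order; preconditions require at least 2
usable secondary genes and a universe of at least twice the list size.

*Topology* builds the feature matrix of input genes × correlates (all
columns, or the 2500 highest-variance ones when the list exceeds 100 genes),
centres rows, reduces with PCA to min(50, rank) components, and clusters the
scores with complete-linkage Euclidean hierarchy. The cluster count is
chosen by maximum mean silhouette over k ∈ 2..min(12, n−1) — an explicit,
overridable rule (`--k`) chosen because silhouette is the least-surprising
generic criterion; labels are relabelled contiguously from 1. t-SNE
(perplexity min(30, (n−1)/3), seeded) is optional; otherwise the first two
PCs serve as the embedding. Identical profiles yield a single cluster with
a warning. *Variant genes* selects the k = 1500 highest-variance correlate
columns (input genes excluded as columns, stable sort so zero-variance
columns lose every tie) and returns the submatrix with row/column dendrogram
orders. No input-list size cap is enforced in the library; the CLI warns
above 500 genes. Static plot files are intentionally not produced: every
figure-shaped result (scatter pairs, null densities, heatmap submatrices,
embeddings) is emitted as a table that plots in one line of the user's
preferred tool.

## Benchmarks

The Pearson/Spearman experiment samples, per simulation, a uniform random
gene set from a collection of co-functional sets and then a uniform random
unordered pair within it (pairs never repeat within a draw, but may across
draws), computes both coefficients on VST rows, and applies a *paired*
one-tailed t-test of mean(pearson − spearman) > 0 — paired because each
simulation yields a matched coefficient pair. The default 2832 simulations
matches the documented experiment size; tests and the acceptance script use
500. Sorting pairs by the difference exposes the Pearson-specific extreme
(tissue-restricted linear relationships) and the Spearman-specific extreme
(monotone non-linear ones).

## Synthetic corpora

For each sample j, each active module m draws a latent factor
`z_jm ~ N(0, latent_sd)`; gene i's mean is
`μ_ij = sf_j · exp(b_i + Σ_m λ_im z_jm)` with loadings uniform on the
module's loading range (zero for non-members), baselines `b_i` log-uniform,
library factors `sf_j` log-normal, and counts negative-binomial with
dispersion `a₀ + a₁/μ`. This single construction produces all three
structures the pipeline assumes: a parametric mean–dispersion trend (for the
normaliser), linear-on-log-scale co-expression (for Pearson), and
group-restricted module activity (for tissue-specific analyses). Modules may
also carry per-group log2 mean shifts to emulate differential expression.

Preset conditions: all presets use 1200 genes and three 60-sample groups
(bone:cancer, bone:normal, brain:normal) with baselines log-uniform on
[500, 30000] — chosen so per-sample totals straddle the 5-million-read
filter realistically — dispersion trend a₀ = 0.05, a₁ = 2, and library-size
log-SD 0.15, values typical of bulk RNA-seq corpora. `strong` plants two
20-gene modules (latent SD 1, loadings 0.35–0.45, giving within-module
r ≈ 0.7 after VST); `null` plants none; `tissue-specific` plants six
10-gene modules, each active in exactly one group with stronger loadings
(0.6–0.9, latent SD 1.5), which produces the pooled-sample pattern where
Pearson clearly exceeds Spearman. Trend-recovery checks use a separate
2000-gene × 100-sample spec with baselines on [1, 1000], where the a₁/μ
term is identifiable.

What the generator does *not* emulate: batch effects beyond library size,
the mean–correlation relationship of real corpora (correlation magnitude
rising with expression), overlapping or hierarchical modules, count sparsity
of single-cell data, and read-level artefacts. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to those real-data pathologies.

A deterministic edge-case metadata table covers every labelling and
filtering boundary: single-cell terms, reads at 4,999,999/5,000,000/
5,000,001, "kidney cortex" descriptions (brain vetoed, kidney assigned),
and groups of 29 vs 30.

## Determinism and problem sizes

Every stochastic operation takes a seed and is bit-reproducible under it;
run manifests record the resolved configuration without timestamps, so
reruns are byte-identical. Test and acceptance problem sizes — 1200-gene
stores, 200–500 calibration repeats, 500 benchmark simulations,
n_perm = 500–1000 — were chosen as the smallest scales at which the
calibration and recovery properties are statistically unambiguous.

## Known limitations

Flat tissue labels (no ontology hierarchy); Pearson/Spearman only (no
biweight midcorrelation or Kendall); no mitigation of the mean–correlation
relationship; gene-label permutation nulls only (no phenotype permutation);
blind VST without design awareness; single-cell data excluded by design.
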