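# Methods

This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic data does and
does not emulate, and the numerical decisions a maintainer should know
about.

## Count simulation

Counts for gene *g* in sample *j* are negative binomial with mean
`lib_j · p_gj` and size (dispersion) *k*, variance `m + m²/k` — the
standard RNA-seq count model. The per-gene relative expression is
`2^(b_g + l_gc + e_gc·[condition ≠ NT])` where `b_g ~ U(range)` is the
baseline log2 level, `l_gc ~ N(0, line_effect_sd)` a per-gene per-line
baseline shift (the "cell-line effect" the adjusted PCA removes), and
`e_gc` the planted knockdown log2 fold change for that line. Effects
are applied multiplicatively on the mean (2^effect) so planted log2FCs
survive CPM normalization; library sizes are drawn uniformly from a
configured interval, which makes CPM normalization non-trivial. One
`numpy` Generator seeded from the config drives the whole draw, so a
seed fully determines the matrix.

Defaults mirror the study design the pipeline targets: 2 cell lines ×
(NT, KD1, KD2) × 2 replicates = 12 samples. Where the design leaves a
value open, the defaults are chosen as typical for bulk RNA-seq at
desk-scale: dispersion k = 10 (moderate overdispersion), library sizes
0.8–1.2 M (scaled-down depth; the per-gene depth at 2 000 genes is
comparable to a 20 M-read library over 20 000 genes), baseline log2
levels uniform on [0, 9], line effect SD 0.5. One field exists beyond
the study design: `noncoding_fraction` (default 0.15) labels a tail of
background genes as `lncRNA` so the protein-coding filter has something
to remove.

The simulator does **not** emulate read-level artifacts (GC bias,
mappability), batch effects beyond the line shift, correlated gene
programs, or heavy-tailed dispersion heterogeneity. Passing tests
therefore demonstrate that the *inference chain* is correct under its
own model assumptions, not that those assumptions hold for any
particular real dataset.

Survival cohorts follow `h(t|x) = h0 · exp(βx)` with exponential event
times, independent exponential censoring, and Gaussian expression;
observed time is the minimum of the two clocks. Defaults
(`h0 = 0.02 /month`, censor rate 0.01) give median follow-up and
censoring fractions in the range typical of oncology cohorts.

## Normalization and PCA

CPM uses the column total over **all** features, computed before the
protein-coding restriction — the order matters because the restriction
changes library sizes. The log transform is `log2(CPM + 1)`, so zero
counts map to exactly zero. No additional low-count filtering and no
gene variance scaling are applied; with mean centering only, low-count
genes contribute little variance to the PCA.

PCA treats samples as observations: each gene is mean-centered across
samples and the centered matrix decomposed by SVD. Component signs are
fixed by making the largest-magnitude loading positive, which makes
scores reproducible across BLAS implementations. The cell-line-adjusted
variant subtracts each gene's within-line mean (exact to the last ulp
by construction), making the result invariant to any per-line per-gene
additive shift; a line with a single sample is rejected because its
adjusted values would be identically zero.

## Differential expression

Fold changes and test statistics deliberately use different scales:
log2FC is computed from arithmetic means of per-sample CPM with a
0.5-count offset (`log2((m̄_KD + 0.5)/(m̄_NT + 0.5))`, finite for all
observed means), while the Welch t test runs on the log2-CPM values.
The CPM scale is recovered exactly from the stored matrix as
`2^v − 1`. The rank statistic is `sign(log2FC) · (−log10 p)`; at
p = 1 it is 0 regardless of fold-change sign, and p-values are floored
at the smallest positive double so the statistic stays finite when the
t distribution underflows. The zero-variance degenerate case (both
groups constant, means differ) receives that same floor and a
`degenerate` flag — it cannot be ranked honestly, but it should rank
ahead of everything that can. Volcano significance is strict
(`p < threshold`) and unadjusted; multiplicity control is intentionally
absent from both the volcano flag and the core-signature filter, whose
concordance requirement is itself the replication filter.

## Core signature, z-scores, clustering, modules

Signature membership requires |log2FC| ≥ threshold (inclusive, default
1) in both lines with equal sign, after intersecting the two DE tables
on gene id; gene-set work downstream uses symbols. Z-scores use the
sample SD (n−1). Constant rows z-score to zeros with a warning rather
than erroring: they are degenerate but displayable. Gene ordering is
the plain left-to-right leaf order of a SciPy average-linkage (UPGMA)
tree over Euclidean distances, without optimal-leaf reordering, so the
order is a pure function of the input. Module gene lists are
configuration (curation, not an algorithm); the shipped defaults are
four seven-gene modules covering the biological axes of the knockdown
response, and module matrices are z-scored per-condition replicate
means in a fixed column order (line 1 NT, KD1, KD2; line 2 NT, KD1,
KD2).

## Preranked GSEA

The running sum adds `|s_i|^w / Σ_members |s|^w` at member genes and
subtracts `1/(N − n)` elsewhere; ES is the extremum by absolute value,
the leading edge the members at or before (positive ES) / at or after
(negative ES) that extremum. Defaults: `min_size 15`, `max_size 500`,
`n_perm 10 000`, weight exponent 1.

Because the input is preranked there is no sample structure to permute;
the null is `n_perm` uniform same-size gene subsets of the ranked
universe. Permuted ES values are computed in O(set size) from hit
positions alone (the walk's extrema can only occur immediately around
hits), and one null is shared per distinct set size. The p-value is
`(1 + #{null ES at least as extreme, same sign}) / (1 + #null same
sign)` — never below the permutation floor — and NES divides ES by the
mean |null ES| of matching sign, handling the two tails separately.
FDR is Benjamini–Hochberg across the tested sets: deterministic and
conservative relative to tail-ratio FDR estimators, and a documented
deviation from what GSEA reference tools compute internally (those
also apply an adaptive p refinement not reproduced here). If all
member scores are zero the hit weights fall back to unweighted steps
rather than 0/0.

## Survival statistics

Kaplan–Meier is the product-limit estimator over distinct event times.
The log-rank test uses the two-group O−E formulation with the
hypergeometric variance. The hazard ratio comes from a one-covariate
Cox partial likelihood with the Efron tie correction, maximized by
scalar Newton iteration (start 0, tolerance 1e-10, |β| > 50 treated as
monotone-likelihood divergence) with the 95% CI from observed
information; a group with zero events short-circuits to HR 0 or ∞ with
a flag. These estimators agree with `lifelines` to ~1e-6 on shared
inputs (checked in the tests, where lifelines serves as the independent
oracle, not the implementation).

Dichotomization defaults to the median split with ties going low —
the conservative choice, since scanning cutoffs for minimal p inflates
significance. The scan (quantiles 0.20–0.80 in 0.05 steps, minimal
log-rank p) is available as `best_cutoff` and labeled exploratory; its
scan table is returned so the optimism is visible. The screen reports
raw log-rank p (which drives the HR > 1, p < 0.05 summary count) plus
a BH-adjusted column, and ranks genes by HR descending with stable
ties.

## Pipeline

One global seed is fanned out to per-stage child seeds via
`numpy.random.SeedSequence.spawn`, so a stage rerun in isolation
reproduces its in-pipeline output. Config validation collects *all*
violations before failing. Outputs are one directory per run with a
subdirectory per stage; `manifest.json` echoes the config and records
gene counts at every filter, which the test suite audits against
recounts of the emitted files. A `_STALE` marker is present while a
run is in progress or after an aborted run. In simulation mode with no
GMT inputs, GSEA runs against sets derived from the planted program
(planted-up, planted-down, random nulls); curated module lists are
intersected with the available symbols and skipped (logged, recorded
in the manifest) when fewer than two members are present.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 600–2 000
simulated genes, 12–18 samples, permutation counts of 200–2 000,
cohorts of 100–2 000 subjects, and 20-seed Monte-Carlo loops. These
sizes put Monte-Carlo error comfortably inside the asserted bands
while keeping the whole suite under a minute; the defaults users see
(`n_perm = 10 000`, full-size gene universes) are the analysis-scale
values.

## Known limitations

- The GSEA FDR is BH over permutation p-values, not the tail-ratio FDR
  of reference implementations; NES values match in sign and
  approximate magnitude, not digit-for-digit.
- Duplicate symbols in a ranked list are an error, not silently
  aggregated; upstream tooling conventions vary and guessing would be
  worse.
- The Cox fit supports exactly one binary covariate — all the screen
  needs — not general design matrices.
- Between-sample normalization is CPM only (no TMM/quantile), matching
  the pipeline's target design, and counts are accepted as given (no
  alignment or quantification).
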