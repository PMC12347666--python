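# Methods

## Scope and model

`markcord` analyzes promoter histone-modification data from a two-condition
replicate design: two groups of animals (here labelled LN, low nutrition,
and HN, high nutrition; four biological replicates each), ChIP coverage for
one or more promoter marks (the activating H3K4me3 and the repressive
H3K27me3 are the built-in defaults), an already-normalized log2 expression
matrix, and optionally a promoter CpG-methylation (beta) matrix. The
pipeline asks three questions:

1. **Where does each mark sit relative to genes?** (metagene profile)
2. **Which promoters are differentially modified between groups?**
   (differential test, DHR/DHG classification, hierarchical clustering)
3. **Which epigenetic modifier best explains expression change?**
   (top-K concordance scoring and modification-vs-expression regression)

All genomic intervals are 0-based half-open (`[start, end)`, the BED
dialect); the TSS of a minus-strand gene is `end − 1`. Inputs printed
1-based inclusive must be converted with
`Interval.from_one_based_inclusive`, never silently.

## Promoter quantification

The functional promoter window is `[tss − W, tss + W)` with `W = 1000` bp
(the −1 kb..+1 kb region around the TSS where trimethylation marks act on
transcription). Per sample,

    level = (Σ value × overlap_bp / window_length) × (10⁷ / library_size)

where `library_size = Σ value × interval_length` over the whole track. The
10⁷ constant (signal per 10 Mb-equivalent of library) is arbitrary but
fixed; only between-group ratios matter downstream. `quantify` is linear in
track values and invariant to splitting intervals — both are tested
properties. Peak-to-TSS adjacency (`tss_adjacent`) is true when a peak
contains the TSS or either end is within `D = 1000` bp of it; `D` is
exposed because "adjacent" has no canonical value.

## Metagene profiles

Scale-regions layout: 30 upstream bins of 100 bp, 60 length-rescaled
gene-body bins, 30 downstream bins of 100 bp (120 bins). Body bin values
are length-weighted mean densities, so bin mass conserves coverage exactly
(`Σ bin_value × bin_width` equals the coverage integral over the padded
span — a tested invariant). Minus-strand genes are mirrored so bin 0 is
always 5′. The 30/60/30 scheme gives 100 bp flank resolution and
percentile-like body resolution; nothing downstream depends on it. An
input-control track, when given, is profiled as its own curve and never
subtracted.

## Differential modification

Per region, replicate levels are transformed `x → log2(x + c)` with
pseudocount `c = 1` on the 10⁷-scaled levels (`c = 0.01` for beta-scale
methylation matrices, which live in [0, 1]) and compared with a two-sided
Welch t-test. Effect sizes:

* `ln_hn_ratio` — linear ratio of untransformed group means (the
  field's reporting scale); `+inf` when the denominator group mean is 0,
  defined as 1.0 when both are 0.
* `log2_ratio` — `log2((mean_LN + c)/(mean_HN + c))`: finite everywhere and
  sign-consistent with the linear ratio by construction.

Degenerate regions: both group variances zero and equal means → p = 1;
zero variances with unequal means → p set to the machine-minimum
placeholder with a logged warning.

**No multiple-testing correction by default.** DHR calls use raw p < 0.05
and DHG clustering p < 0.01; this mirrors how such thresholds are commonly
reported for small-replicate ChIP designs and keeps counts comparable to
that convention. It is a *faithful-reproduction* choice, not a statistical
recommendation: with 10% true effects, a raw p < 0.05 cut has an expected
false-discovery proportion near 30% regardless of sample size.
Benjamini–Hochberg adjustment is available (`adjust="bh"`), and the
validation suite uses the BH call set whenever an FDR bound is asserted.

Welch at 4-vs-4 has true size ≈ 0.041 at nominal α = 0.05 (the
Welch–Satterthwaite degrees-of-freedom estimate is conservative at tiny n).
The null-calibration scenario therefore estimates the rejection rate by
pooling many replicate null datasets rather than trusting one noisy
2000-gene estimate.

Hierarchical clustering of DHGs uses distance 1 − Pearson correlation
(across samples for genes, across genes for samples), unweighted average
linkage, with regions pre-sorted lexically so ties break deterministically.
Zero-variance rows get distance 1 to everything (logged). The k = 2 cut of
the sample dendrogram is compared against the true group labels in the
validation suite.

## Concordance scoring

For each modifier the top K = 20 genes by differential-modification p are
selected (ties: |log2 ratio| descending, then gene id; genes absent from
the expression matrix are skipped and the next rank promoted; for site-level
CpG tables each gene is represented by its best site). Each gene is then
classified against the expression comparison (Welch, two-sided, on the
log2 matrix):

* `significant`: expression p < 0.05. p < 0.10 is recorded as a trend but
  never counts toward consistency.
* `consistent`: significant *and* the expression change points the way the
  modification predicts — same sign for an activating mark, opposite for a
  repressive one. A zero expression or modification change is inconsistent.
* `high_fc`: |linear expression fold change| ≥ 1.5, i.e. |log2 ratio| ≥
  log2 1.5 ≈ 0.585.

The modification axis used for classification and regression is **log2 of
the linear LN/HN ratio**, not the pseudocounted test effect: the ratio is
the scale the concordance indices are defined on, and the pseudocount
visibly attenuates large effects at typical level magnitudes (a planted
slope of 1.0 reads as ≈ 1.15 when regressed on the pseudocounted effect).
Genes whose ratio is undefined (a zero group mean) are excluded from the
records and counted separately.

Per modifier, ordinary least squares of expression log2 ratio on
modification log2 ratio is fitted over the consistent genes with a free
intercept (whether the underlying procedure forces the origin is not
knowable; a free intercept is the conservative choice and the fitted
intercept is reported). R² is omitted when fewer than 3 consistent genes
exist or the response has zero spread. Modifiers are ranked by
`(n_high_fc_consistent, n_consistent, R²)`, descending and in that order —
"how often does the modifier produce large, direction-correct, significant
expression changes" before goodness of fit.

## Enrichment

Hypergeometric upper-tail test of a gene list against a user-supplied
term→gene table. The background is every gene annotated with ≥ 1 term (the
convention of desktop annotation tools), not the whole gene universe. Fold
enrichment is `(k/n)/(K_term/N)`. Raw p < α extraction by default, BH
behind a flag; the EASE variant (replace k by k − 1 in the tail) is offered
but off by default. The closed form is verified against exhaustive draw
enumeration for all universes of size ≤ 12.

## Synthetic data generator

`simulate_dataset(SyntheticConfig(...))` emulates the 4-vs-4 two-mark study
design end to end: BED6 gene models laid out on a synthetic chromosome
(10 kb spacing, 2–6 kb bodies, random strands), bedGraph coverage per
sample and mark, a flat input track, a log2 expression matrix, a
methylation beta matrix, a term→gene annotation table with a few terms
enriched in the planted gene set, and a `truth.tsv` sidecar with every
planted effect. The same config (seed included) reproduces every output
byte — tested by hashing.

Statistical structure and default conditions:

| parameter | default | rationale |
|---|---|---|
| `n_reps_per_group` | 4 | the emulated design |
| `frac_dhg`, `frac_dmg` | 0.10 | planted fraction per mark; mark and methylation gene sets are disjoint (methylation targets different genes than the histone marks) |
| `effect_log2` | 1.0 | top-ranked promoter changes in this kind of design have linear LN/HN ratios ≈ 0.26–3.6, i.e. \|log2\| ≈ 0.25–1.9 with median ≈ 1 |
| `baseline_log_mean`, `baseline_log_sd` | ln 300, 1.0 | promoter-window fragment counts at ~30 M reads/sample |
| `nb_dispersion` | 0.01 | counts are NB with var = μ + φμ²; chosen so top-ranked planted promoters separate cleanly from the best-of-n null p floor (rank-20 p ≈ 1e-4..1e-3, matching the p-value scale such studies print for their top-20) |
| `coupling_slope_activating` | +1.0 | activating mark: expression follows modification |
| `coupling_slope_repressive` | −0.3 | weak repressive coupling: repressive-mark top genes shift expression well below the 1.5-fold bound |
| `meth_coupling_slope` | 0.0 | methylation decoupled from expression by default |
| `expr_noise_sd` | 0.04 | gene-level deviation from the linear coupling |
| `expr_rep_sd` | 0.07 | replicate noise on the log2 expression scale |

The two expression noise scales are deliberately tight: they give a
≥ 4.5 σ margin between the repressive-mark expression shift (0.3 · 1.0) and
the 1.5-fold bound (0.585), so "the repressive mark and methylation produce
no large concordant expression changes" is a structural property of the
default conditions rather than a per-seed coin flip. Consequence worth
knowing: with replicate SE ≈ 0.05 the repressive-mark shifts *are*
statistically significant in the default scenario — the qualitative
contrast the scenario preserves is the absence of *large* (>1.5-fold)
expression changes, not the absence of significance.

What the generator does **not** emulate: read-level data (no FASTQ, no
fragment-length or peak-shape realism — promoter coverage is uniform over
the ±1 kb window on a flat background), mappability and GC structure,
between-sample composition biases beyond library size, loose biological
coupling between chromatin state and expression, and correlated
gene-gene structure. Passing tests therefore demonstrate that the
*procedures are correct and calibrated under their own assumptions*, not
that real tissue ChIP data will behave this cleanly.

## Numerical and degenerate-input choices

* Pseudocounts: 1 on 10⁷-scaled levels, 0.01 on beta matrices; both
  configurable and recorded in results.
* Zero-variance regions/rows and zero group means follow the explicit
  contracts above rather than propagating NaN.
* Missing matrix cells (`NA`) stay missing — regions with missing values
  are dropped from a test with a logged count, never imputed as zero.
* Clustering tie-breaks: regions sorted lexically before linkage;
  correlation distances symmetrized and clipped to [0, 2].
* Phenotype-style group ratios round half-up to 2 decimals (the reporting
  convention for such tables).
* Seeds: a config's single integer seed drives one `numpy` Generator
  through a fixed draw order; validation scenarios derive per-replicate
  seeds as `seed + i`.

## Validation scenario sizes

The validation suite (and `scripts/acceptance.py`) uses problem sizes
chosen to keep each scenario's estimator precise at interactive runtimes:
null calibration pools 40 replicate 2000-gene null datasets × 2 marks
(≈ 5 × 10⁻⁴ standard error on the rejection rate, ~4 s); recovery runs
1000 genes with the planted effect raised to 1.5; coupling recovery runs
400 genes in a near-noiseless regime (noise SDs 0.01, dispersion 0.001);
ranking, clustering and profile checks run 200–500 genes under default
conditions. The whole script finishes in well under a minute.

## Known limitations

* The Welch test at n = 4 is conservative (true size ≈ 0.041 at α = 0.05);
  no moderation/shrinkage across regions is attempted.
* Raw-p DHR/DHG thresholds do not control FDR (see above).
* Quantification uses fixed TSS windows by default; quantifying over called
  peak extents is supported by supplying peak intervals as regions, but no
  peak caller is included.
* Concordance measures association, not causation; with K = 20 the
  per-modifier summaries have wide sampling variability on real data.
* The input control is reported alongside profiles, never used for
  background correction.
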