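# markcord

Promoter histone-mark analysis for two-condition replicate designs:
quantification of ChIP signal (H3K4me3, H3K27me3, …) in strand-aware
windows around the TSS, differential modification between two replicate
groups, TSS metagene profiles, epigenome–transcriptome concordance scoring
per epigenetic modifier, and hypergeometric term enrichment — plus a
synthetic-data generator with planted ground truth for calibration and
parameter-recovery testing.

The package is written for the classic developmental-programming study
layout: two maternal-nutrition groups ("LN" low vs "HN" high, n = 4 fetuses
each), promoter ChIP-seq for an activating mark (H3K4me3) and a repressive
mark (H3K27me3), an expression matrix from the same animals, and promoter
CpG-methylation calls. It answers the question such studies pose: *which
epigenetic modifier actually moves gene expression, and by how much?*

## The statistics at the core

* **Promoter level.** For gene *g* and sample *s*, signal in the window
  `[tss − W, tss + W)` (default W = 1 kb) is summarized as library-scaled
  density: `level = (∫ coverage / 2W) · 10⁷ / library_size`.
* **Differential modification.** Per promoter, a two-sided Welch t-test on
  `log2(level + 1)` between the groups; effect sizes are the linear LN/HN
  ratio of group means and `log2` of its pseudocounted version. Raw
  p-thresholds (p < 0.05 regions, p < 0.01 for clustering) by default,
  Benjamini–Hochberg behind a flag.
* **Concordance.** For each modifier, take the top K = 20 genes by
  differential-modification p; a gene is *consistent* when its expression
  change is significant (Welch p < 0.05) **and** points the way the mark's
  polarity predicts (activating: same sign; repressive: opposite), and
  *high-FC* when |expression fold change| ≥ 1.5. Per modifier the package
  reports (n consistent, n high-FC consistent, OLS slope/R² of expression
  log2-ratio on modification log2-ratio over the consistent genes) and
  ranks modifiers by those counts.
* **Enrichment.** Hypergeometric upper tail of a gene list against a
  user-supplied term→gene table, with fold enrichment
  `FE = (k/n)/(K_term/N)`.

See `docs/methods.md` for assumptions, parameter rationale, degenerate-case
contracts and limitations.

## Worked example

Simulate a default-condition dataset (500 genes, 4 vs 4 replicates, 10%
planted differential promoters per mark), fit the differential model for
H3K4me3, and score concordance for all three modifiers:

```python
from markcord import SyntheticConfig, simulate_dataset, DifferentialMark, promoter_windows
from markcord.concordance import ConcordanceAnalysis
from markcord.diffmark import diff_test

ds = simulate_dataset(SyntheticConfig(seed=42, n_genes=500))
windows = promoter_windows(ds.genes, window=1000, chrom_sizes=ds.chrom_sizes)

model = DifferentialMark.from_tracks(ds.tracks["H3K4me3"], windows, mark="H3K4me3")
res = model.fit(alpha=0.05)
print(res.summary())

tables = {
    "H3K4me3": res.table,
    "H3K27me3": DifferentialMark.from_tracks(ds.tracks["H3K27me3"], windows).fit().table,
    "CpG": diff_test(ds.methylation, ds.groups, pseudocount=0.01),
}
print(ConcordanceAnalysis(ds.expression, ds.groups, tables).fit(k=20).summary())
```

Output:

```
Differential modification (H3K4me3): LN vs HN
regions tested: 500
significant at p<0.05: 26 up, 40 down, 434 ns

         mean_LN  mean_HN  ln_hn_ratio  log2_ratio   p_value direction
gene_id
g227        21.9    10.74        2.039      0.9639 1.586e-07        up
g016       57.03    28.88        1.975      0.9578 1.158e-06        up
...

Concordance of epigenetic modification with expression change (top K=20, expr alpha=0.05, FC>=1.5)

      modifier   K  n_significant  n_consistent  n_high_fc_consistent  r_squared   slope
rank
1      H3K4me3  20             20            20                    20     0.9904  1.0154
2     H3K27me3  20             19            19                     0     0.9349 -0.2712
3          CpG  20              1             1                     0        NaN     NaN
```

Reading it: 66 of 500 promoters are called differentially H3K4me3-modified
at raw p < 0.05 (50 were planted; a raw-p cut admits ~5% of the nulls).
The concordance table recovers the planted structure — the activating mark
drives large, direction-consistent expression changes (all 20 top genes
high-FC consistent, fitted coupling slope ≈ 1.0), the repressive mark
shifts expression the right way but never past 1.5-fold (slope ≈ −0.27,
close to the planted −0.3), and methylation is decoupled — so H3K4me3
ranks first.

The same steps run from the shell:

```sh
markcord simulate --seed 42 --out data/
markcord quantify --genes data/genes.bed --tracks tracks.tsv --out mm.tsv
markcord diff --markmatrix mm.tsv --groups data/groups.tsv --out diff.tsv
markcord profile --genes data/genes.bed --tracks tracks.tsv --out profile.tsv
markcord run --config run.yaml        # whole pipeline + manifest.json
```

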