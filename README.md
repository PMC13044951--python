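# k79zones

Analysis of **state-specific H3K79 methylation zones** in budding yeast from
multi-mark ChIP-seq.

H3K79 can be mono-, di- or tri-methylated (me1/me2/me3), all three states
deposited by the methyltransferase Dot1. Genome-wide, each state
preferentially marks a distinct, largely non-overlapping set of gene bodies.
`k79zones` implements the full numeric surface of that analysis for
epigenomics researchers who want to classify genes into methylation zones,
ask how trans-histone crosstalk mutants (loss of Rad6-mediated H2B
ubiquitination, loss of Sas2-mediated H4K16 acetylation) redistribute
methylation states across zones, track zone stability between growth
conditions, and integrate zone identity with differential expression. A
synthetic-data generator with per-gene ground truth makes every stage
testable end to end without any external download.

## The classification rule

For each gene *g*, the mean gene-body coverage of each mark is computed in
RPM units (reads per 10 million mapped) and normalized to histone H3:

```
s_k(g) = log2( (RPM_k(g) + c) / (RPM_H3(g) + c) ),   k in {me1, me2, me3},  c = 0.5
```

averaged over biological replicates. Gene *g* is assigned to the **meX
zone** when state X exceeds both other states by

```
log2FC(X / Y) > 0.25   and   BH q < 0.5      for both Y != X
```

where the per-gene p-value comes from a paired Wilcoxon signed-rank test on
window-level log2 differences (gene-body windows x replicates as
observations) and q is Benjamini–Hochberg-adjusted across genes per
contrast. Genes failing every zone test fall into **Mixed I**
(me2 ≈ me3 > me1), **Mixed II** (me1 ≈ me2 > me3) or *ambiguous*.

Downstream stages reuse the same gene-body log2 ratios:

* **Redistribution** (`ZoneShiftModel`): per (zone, state), the median
  mutant−WT difference of s_k (effect size, reported as a fold change
  2^|median|) with a two-sided Wilcoxon rank-sum significance level.
* **Dynamics** (`ZoneDynamics`): reclassification under a second condition,
  stable/dynamic status per gene, transition matrix, per-origin stability
  and net flow per destination zone.
* **Expression integration** (`DEModel` + `zone_de_crosstab`): thresholded
  DE calls (1.4-fold, BH q < 0.5, Welch t on log2 expression) cross-tabulated
  against zone labels.

## Worked example

```python
import k79zones as kz

config = kz.GeneratorConfig(seed=1)              # 1500 genes, defaults
genes, truth = kz.generate_genome(config)
sheet = kz.build_sample_sheet(config)
tracks = {s: kz.normalize_depth(t)
          for s, t in kz.simulate_tracks(genes, truth, sheet, config).items()}
table = kz.build_state_table(tracks, sheet, genes,
                             genotype="WT", condition="plusN")
result = kz.ZoneClassifier(table, lfc_min=0.25, q_max=0.5).fit()
print(result)
print("accuracy vs truth:", round(kz.zone_accuracy(result.calls, truth), 3))
```

prints

```
Zone classification (WT, plusN): lfc_min=0.25, q_max=0.5, n=1500
     zone   n  median_dom_vs_runnerup  median_lfc_me3_vs_me2  median_lfc_me3_vs_me1  median_lfc_me2_vs_me1
      me3 434                0.776363               0.776363               1.774280               0.994292
      me2 182                0.457634              -0.770291              -0.296666               0.461617
      me1 422                0.911988              -0.993408              -1.899671              -0.911988
   MixedI 230                     NaN              -0.003566               0.594577               0.593338
  MixedII 232                     NaN              -0.571587              -0.579474               0.002133
ambiguous   0                     NaN                    NaN                    NaN                    NaN

accuracy vs truth: 0.981
```

Each row is one class: `n` genes were called into it, and
`median_dom_vs_runnerup` is the median log2 fold-change of the dominant
state over the stronger of the two other states within the called genes —
the key separation statistic per zone. The generator placed those medians at
0.778 (me3 zone), 0.443 (me2) and 0.897 (me1); the pipeline recovers them
from noisy coverage within a few hundredths, and 98% of zone-class genes are
assigned back to their true zone.

The same analysis runs from the shell over on-disk bedGraph/BED/TSV inputs:

```bash
k79zones all --out run1 --seed 1        # simulate + quantify + classify +
                                        # contrast + dynamics + integrate + report
cat run1/report/zone_summary.tsv
```

## Layout

```
src/k79zones/
  genome_io.py    BED6 / GFF3 / bedGraph / chrom.sizes / sample sheet I/O
  synthetic.py    generator: genomes, coverage, expression, ground truth
  quant.py        RPM normalization, gene-body signal, metagene matrices
  classify.py     ZoneClassifier -> ZoneClassificationResult
  contrasts.py    ZoneShiftModel, fold conversion, rank-sum, outlier ranking
  dynamics.py     ZoneDynamics -> transitions, stability, net flow
  expression.py   DEModel, zone x DE crosstab
  pipeline.py     on-disk stage orchestration with manifests
  cli.py          `k79zones` command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
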