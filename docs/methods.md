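# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Coordinates, binning and units

All genomic intervals are 0-based half-open internally (BED convention);
GFF3 input is shifted by one on read. A single convention everywhere avoids
off-by-one drift between annotation, coverage and quantification. Coverage
is stored as fixed-width binned signal (default **50 bp**), fine enough to
resolve sub-gene spatial structure at yeast gene scale (typical bodies
0.5–2.5 kb) while keeping synthetic tracks small; every downstream quantity
is a mean over windows at least as large as a gene body, so per-base storage
would buy nothing. Bin values are per-base means, so binning conserves
signal mass exactly and partial-bin overlaps are handled by length
weighting.

Depth normalization scales every bin by `1e7 / total_raw_reads` ("RPM" here
means reads per 10 million mapped). The full analysis is invariant to
multiplying any sample's raw counts and total by a common factor.

## Gene-body signal and H3 normalization

Per gene and replicate, the mean RPM over the body `[TSS, TES)` is computed
for each mark (flanks excluded; flanking behaviour is analysed only through
metagene profiles). Methylation states are expressed relative to histone H3
occupancy as `log2((state + c) / (H3 + c))` with pseudocount **c = 0.5
RPM** — small against the working signal range (tens of RPM) and sufficient
to bound log-ratios on empty genes. Replicates are quantified separately and
averaged on the log2 scale, which keeps the ratio interpretation symmetric
under swapping numerator and denominator.

Metagene (scale-regions) matrices use 1 kb flanks in fixed 50 bp bins and a
body resampled to 100 length-weighted bins, oriented 5'→3' (minus-strand
rows reversed). Genes with bodies shorter than one bp per body bin are
dropped with a warning.

## Zone classification

The rule is exactly the thresholded pairwise comparison described in the
README: a state wins a zone when it beats both others by log2FC > 0.25 with
BH q < 0.5 on both contrasts, strict inequalities at both thresholds. The
q < 0.5 cutoff is deliberately lenient and configurable.

The per-gene evidence model deserves explanation because a two-replicate
design carries almost no between-replicate information. Each gene body is
split into `max(2, length // 200 bp)` equal windows; the paired
log2-difference of two states over all windows × replicates feeds a
two-sided Wilcoxon signed-rank test. The exact null distribution is used
when the differences are tie-free and few (n ≤ 25); otherwise the normal
approximation with continuity correction. (scipy's automatic fallback for
tied differences is an exhaustive permutation enumeration — correct but
orders of magnitude too slow at genome scale.) All-zero differences give
p = 1; degenerate cases fall back to a paired t-test with the variance
floored at 1e-8 on the log2 scale; genes with fewer than four paired
observations get p = 1 and a low-evidence flag. BH runs across genes
separately per contrast by default (pooling all three contrasts is exposed
as an option).

Mixed assignment order is deterministic: zones first, then Mixed I, then
Mixed II, then ambiguous. A gene satisfying both Mixed patterns (possible
only when every pairwise gap is inside the tie band with inconsistent
signs) lands in Mixed I by that order.

The per-zone summary reports the median log2FC of the dominant state over
the **runner-up**, where the runner-up is decided per gene as the larger of
the two non-dominant states (equivalently, the smaller of the dominant
state's two pairwise log2FCs).

## Redistribution (mutant vs WT)

Zones are fixed by the WT classification; reclassifying the mutant is a
separate dynamics run. The effect size per (zone, state) is the median of
paired per-gene differences of replicate-averaged log2(state/H3), reported
alongside `2^|median|` as a fold change with a direction flag. Significance
uses the unpaired two-sided Wilcoxon rank-sum on the two per-gene
distributions — the field's conventional annotation for these box-plot
contrasts — even though the gene sets are shared; the paired median remains
the estimator.

`wilcoxon_rank_sum` uses the exact distribution for combined n ≤ 20 without
ties, an exact midrank enumeration for combined n ≤ 14 with ties (so
identical multisets give p = 1 exactly), and the tie- and
continuity-corrected normal approximation otherwise.

Covariate ranking (`rank_outliers`) sorts genes by any quantified covariate
(H2Bubi, Dot1, Rpb3, …) descending, ties broken by gene id, and contrasts
mean log2(state/H3) inside versus outside the top-n set. The default top-n
marks the elbow of the covariate curve (maximal discrete second
difference, bounded away from the ends); published analyses of this kind
pick data-dependent subset sizes, so the parameter is free and logged.

## Zone dynamics

Two classifications made with identical thresholds (enforced) are paired
per gene; any label change, including into a Mixed class, is dynamic. A
zones-only mode restricts origins to {me3, me2, me1} for tabulations that
consider only the three zones. Net flow per destination is
inflow − outflow among off-diagonal transitions; flows sum to zero by
construction.

## Differential expression and integration

The DE engine is intentionally transparent: Welch's t on log2(value + 0.5)
per gene, BH across tested genes, and the thresholded status rule
(1.4-fold and q < 0.5). Genes lacking expression > 0 in both groups are
excluded. Zero-variance groups (exact replicate ties, common in synthetic
fixtures) get the variance floored at 1e-8. The zone × DE cross-tab keeps
raw counts and derives every percentage from them (nearest-integer
rounding), so reported percentages can never drift from the stored counts.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
per-gene ground truth for recovery testing.

**Genome.** Genes are packed on synthetic chromosomes (default 400 kb, up
to 16) with ≥ 2 kb spacing so 1 kb flanks never overlap, lengths uniform on
500–2500 bp rounded to the bin width, strands alternating. Gene boundaries
fall on bin boundaries, which lets noise-free runs reproduce configured
quantities to machine precision.

**Signal model.** Each zone has a (dominant, runner-up, third) state
ordering; the per-gene dominant-over-runner-up effect is drawn
`Normal(zone_effect_median, effect_spread)` on the log2 scale, so the
configured value is both mean and median. Defaults for the medians are
0.778 / 0.443 / 0.897 log2 units (me3 / me2 / me1 zones). The third state
sits a fixed gap below the runner-up: 1.0 log2 in the me3 and me1 zones
(the two states are strongly anti-correlated in each other's zones) and 0.3
in the me2 zone (where the minority states are comparable, me3 slightly
lower so the runner-up identity is stable). Mixed classes place their
co-dominant pair at equal level above the third state (gap 0.6). A per-gene
amplitude `Normal(0, 0.25)` shifts all states together (it cancels in
pairwise contrasts but moves absolute levels realistically).

**Why effect_spread defaults to 0.12.** Zone medians are summarized over
*called* genes, and the lfc > 0.25 gate truncates the low tail of the
effect distribution. The truncation bias on the recovered median grows with
the spread: at spread 0.3 the me2-zone recovered median is inflated by
~0.1 log2 units (a quarter of a Normal(0.443, ·) effect distribution sits
below the gate), while at 0.12 the bias is ~0.02 — below the sampling error
of the median at realistic zone sizes. The default therefore keeps
configured medians recoverable; wider spreads remain available and are
exercised by the accuracy tests.

**Spatial profiles.** Each (zone, state) pair has a smooth shape over
[−1 kb flank | scaled body | +1 kb flank]: a mid-body bump for me3 in its
zone, broad body plateaus for me1/me2 in theirs, a flank-elevated and
body-flat shape for me1 in the me3 zone, moderate profiles elsewhere, flat
H3. Shapes are normalized to unit body mean, and per-gene bin values are
rescaled so the realized gene-body mean equals the configured level exactly.

**Calibration to the analysis scale.** Target means are placed on the
pseudocounted ratio scale, `mean = (base + c)·2^offset − c` with the base
H3-level signal 60 RPM (the middle of the working heatmap range) and c the
quantifier's pseudocount. Without this, `log2((s+c)/(h+c))` would differ
from the configured offset by a few thousandths and noise-free runs could
not reproduce configured medians exactly.

**Noise.** Per-bin raw counts are negative binomial with a single shared
dispersion (default **10**), the standard overdispersion model for ChIP
coverage; `dispersion = inf` gives the Poisson limit. `noise_free = True`
produces the expected counts deterministically and zeroes all gene-level
variation — the mode in which classification recovers every gene and every
configured median exactly. PRNG substreams are keyed by (seed, sample,
chromosome), so adding samples never perturbs existing draws.

**Genotype effects.** A mutant shifts (zone, state) cells of the log2 level
table. Defaults: loss of Rad6-mediated H2B ubiquitination (`rad6d`) strongly
depletes me1 in the me1 zone (−1.44), mildly depletes me2 in the me2 zone
(−0.601), ectopically deposits me1 (+1.42) and me2 (+0.328) in the me3
zone, and removes me3 from its own zone (−3.0; this last magnitude is a
synthetic stand-in — bulk near-complete loss with no published genome-wide
number). Loss of Sas2 H4K16 acetylation (`sas2d`) is a weaker version of
the same pattern (−1.11 me1-zone me1, +0.415 me3-zone me1).

**Condition switching and expression.** Under a second condition each gene
keeps or switches its zone per an (origin → destination) fraction table;
defaults keep ~2/3 of genes stable, me3-origin genes most stable, with net
flow biased toward the me2 zone. Expression is log-normal per gene with a
condition effect and a mutant × DE-status shift applied under the second
condition; per-zone DE fractions default to mostly-down in the me3/me2
zones and an even split in the me1 zone, with effect 1.2 log2. Replicate
noise is 0.15 log2 — within the realistic range for yeast RNA-seq
biological replicates, and small enough relative to the 1.4-fold threshold
that the configured zone × DE proportions are recoverable (at 0.25 the
lenient thresholds admit ~6% false calls with two replicates, which dilutes
the crosstab away from its configured proportions).

**What the generator does not emulate.** No read-level simulation (no
FASTQ/fragments), no mappability or GC structure, no spatially correlated
noise along chromosomes, no antibody efficiency differences between marks,
no copy-number or nucleosome occupancy variation, and H3 is flat rather
than nucleosome-patterned. Passing recovery tests therefore demonstrates
the correctness and calibration of the analysis pipeline on data satisfying
its assumptions — not robustness to every artefact of real ChIP-seq.

## Problem sizes in the test suite

The suite exercises full-pipeline recoveries at 1500 genes (zone medians,
accuracy), ~1700 genes across WT + rad6d cohorts (redistribution), and 900
genes across two conditions (dynamics) — sizes at which median sampling
error is a few hundredths of a log2 unit, comfortably inside the asserted
tolerances, while the whole suite stays fast on one CPU. Fixed seeds make
every assertion reproducible.

## Known limitations

* The DE engine is a deliberately simple Welch-t replacement for a
  count-model tool; only the thresholded integration logic is of interest
  here, and absolute power at two replicates is modest.
* The rank-sum significance annotation treats WT and mutant gene sets as
  independent samples although they share genes; the paired median is the
  quantitative estimator.
* The evidence model's window observations are spatially correlated within
  a gene (profile shape), so per-gene p-values are approximate; the lenient
  q threshold makes the classification insensitive to this.
* Zone counts on real data depend on the annotation and read-processing
  stack upstream of this package; the annotation file is treated as
  authoritative input.
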