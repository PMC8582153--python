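# Methods

## Coordinate conventions

All intervals are 0-based half-open (BED convention).  GTF input (1-based
closed) is shifted at the reader boundary and nowhere else.  A gene's TSS is
its 5' end: `start` on the + strand, `end - 1` on the − strand.  Genes are
the unit of analysis; multi-transcript structure collapses to one TSS per
gene id (the annotated gene 5' end).

## Promoter windows and peak context

The promoter of a gene is the symmetric window `[tss − flank, tss + flank)`
with `flank = 3000` bp by default, clipped at the contig origin (so a
window is shorter than `2·flank` only there).  Strand determines which gene
end is the TSS, not the window shape.  Peak context is assigned with
precedence **promoter > intragenic > intergenic**: any ≥ 1 bp overlap with
any promoter window makes a peak a promoter peak, assigned to *all* genes
whose windows it touches (a `nearest_only` switch restricts to the nearest
TSS); otherwise overlap with any gene body makes it intragenic; otherwise
intergenic.  The TSS distance is measured from the peak midpoint and signed
relative to the TSS strand.  No fractional-overlap rule is used: the ≥ 1 bp
threshold is the minimal assumption and is configurable.  Interval queries
use an interval tree plus a sorted TSS array; both are property-tested
against exhaustive scans, so the index is an optimization, never a
semantics change.

## Distal (enhancer-linked) binding

Peaks whose |TSS distance| exceeds the promoter flank are matched against
the enhancer anchors of a Capture Hi-C-style interaction map (BEDPE + gene
labels on the promoter anchor).  A ≥ 1 bp anchor overlap contributes all of
that pair's genes.  The *distal-only* target set is the set difference
against the promoter-bound union, so a gene never carries both labels.  No
interaction-score threshold is applied by default (a `--min-score` option
exists): published enhancer–promoter maps are already thresholded by their
authors, and an extra cutoff would be a silent second filter.

## Differential expression

Genes are kept when CPM > 1 in ≥ 3 samples (CPM = count·10⁶ / library
size); expression is log2(CPM + 0.5).  A per-gene linear model
`logexpr ~ condition + cell_line` is fitted by OLS jointly over both cell
lines — the blocking covariate absorbs line-specific baseline shifts while
the knockdown contrast is shared.  Variance moderation follows the
empirical-Bayes scaled-inverse-chi-square model: with per-gene residual
variance s²_g on d df,

    E[log s²_g]  = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2)
    Var[log s²_g] = ψ′(d/2) + ψ′(d₀/2)

so d₀ solves `ψ′(d₀/2) = Var(log s²) − ψ′(d/2)` by Newton inversion of the
trigamma function and s₀² follows from the mean equation.  When the
observed spread of log variances does not exceed the chi-square sampling
spread, d₀ = ∞ and all genes share s₀² (full pooling); d₀ = 0 recovers the
ordinary t-test.  The moderated t uses the posterior variance
`(d₀ s₀² + d s²_g)/(d₀ + d)` on d₀ + d df.  The implementation is
cross-validated against R limma's `lmFit`/`eBayes(trend = FALSE)` in the
test suite; limma is an oracle there, never a dependency.

**Precision weights are deliberately not used.**  The mean–variance trend
correction (voom) matters most for very low counts; with the CPM filter in
place, constant-variance moderation on log2-CPM (the "limma-trend" style)
preserves the calibration and power this package needs, at a fraction of
the complexity.  The type-I-error test pins the consequence: the realized
false-positive rate at α = 0.05 stays inside [0.04, 0.06].

Regulation calls use strict inequalities |logFC| > 0.1 and adj. P < 0.05
(BH step-up across all tested genes).  Sign convention, stated once and
used everywhere: the contrast is knockdown − control, so `down` after
knockdown ⇒ the TF was sustaining the gene ⇒ *positively regulated*;
`up` ⇒ *negatively regulated*.

## Clinical support

The correlation screen computes Pearson r of each gene row against the TF
row, with p from `t = r·√((n−2)/(1−r²))` on n − 2 df, two-sided, keeping
p < 0.01; the TF row is excluded and zero-variance rows are skipped.  The
screen defaults to GCB-subtype samples when run through the pipeline, since
correlation support is sought in the subtype under study.  Clinical support
for a target additionally requires **sign concordance**: positive
regulation ↔ r > 0 (a flag disables this).  The subtype association uses a
median split of TF expression (ties to "low": `> median` is high) and a
two-sided Fisher exact test on the high/low × GCB/ABC table, with a Haldane
0.5 correction for the odds ratio when a cell is zero.  Fisher's exact test
is used rather than chi-square because it is valid at every cell count;
its conservatism at small n is acknowledged (the type-I test asserts the
rejection rate is ≤ nominal, not equal to it).

## Evidence tiers

A direct target starts at tier 1 (binding + DE); concordant clinical
correlation and essential-gene membership each add one, so tier ∈ {1, 2, 3}
counts evidence.  The two flags are also reported independently —
essentiality is not conditioned on clinical support, so the tier-3 count is
not nested inside tier 2.  Every summary count is a recomputed set size;
no count is derived from another.

## Motif enrichment

The bundled default PWM is a width-9 ETS-family core (GGAA/T-centered);
any JASPAR-format matrix is accepted.  Scores are log2 odds against a
uniform background with pseudocount 10⁻³; both strands are scanned and the
default hit threshold is 80% of the maximum achievable score.  Windows
containing N are skipped.  Enrichment compares the fraction of sequences
with ≥ 1 hit between peaks and a size-matched background of per-sequence
dinucleotide shuffles, by two-sided Fisher exact test.  The shuffle is the
Altschul–Erikson Eulerian-path construction (random arborescence toward the
terminal base via Wilson's loop-erased walk, then per-vertex edge
permutation), which preserves each sequence's dinucleotide counts exactly —
property-tested, not approximately.

## Over-representation analysis

Upper-tail hypergeometric `P(X ≥ k)` per gene set with BH adjustment across
the collection.  The universe is the *expressed* universe — genes passing
the CPM filter — not the whole annotation, which is standard ORA practice
and avoids inflating enrichment with never-expressed genes.  Query genes
outside the universe are dropped with a warning; sets empty after universe
intersection are dropped before testing.

## Synthetic data generator

The generator emulates the statistical structure of the emulated study
design, not its genome: 2,000 genes on 4 chromosomes (50 kb spacing, gene
lengths 2–10 kb, random strand), two cell lines × {knockdown, control} × 3
replicates, and 150 clinical samples (75 GCB + 75 ABC).  Planted categories
(defaults): 40 + 40 promoter-bound direct targets (positive/negative
regulation), 10 + 10 distal-only targets, 100 indirect responders (DE
without binding), 200 bound-but-unresponsive null genes, one TF gene, rest
null.

* **Peaks.**  Promoter targets get a 200–600 bp peak overlapping their
  ±3 kb window in ≥ 1 cell line; distal targets get a peak inside an
  enhancer anchor ~20 kb from their TSS, linked back to the promoter in
  the interaction map, and never a promoter peak.  500 background peaks
  are placed away from every promoter window and enhancer anchor, about
  half inside gene bodies so the context mix (promoter/intragenic/
  intergenic) resembles real TF peak sets.  Decoy interaction pairs with
  no peak exercise the negative path of the linkage.
* **Counts.**  Negative binomial via Gamma–Poisson mixing (dispersion
  0.05; 0 degenerates to Poisson), log-normal baselines (median 150
  counts; planted targets floored at 50 so regulation is observable above
  the CPM filter), a mild per-gene cell-line effect (so the blocking
  covariate is exercised), ±20% library-size jitter, knockdown effect
  ±1 log2 unit (TF itself −2).
* **Clinical matrix.**  One latent standard-normal factor per sample
  drives the TF row (GCB mean 6.0, ABC 5.2, unit variance — planted signal
  for the dichotomization test) and each clinically supported target at
  the planted correlation (0.6, sign matching regulation; 60% of each
  direct category is supported).  All other genes are independent.
* **Sequences.**  Peak-region sequences are uniform random with the ETS
  consensus planted in true-target peaks only.
* **Essential genes.**  30% of positively regulated direct targets plus 40
  random null genes, mirroring the asymmetry that essentiality enriches
  among genes the TF sustains.

All randomness flows from a single seeded generator; the bundle is
byte-identical across runs with the same seed.  A validator re-reads every
file and asserts the truth invariants (promoter targets bound, distal
targets linked and promoter-free, indirect genes unbound, category counts).

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: read-level noise and mapping artifacts, peak
width/shape and caller score distributions, correlated gene–gene expression
structure (co-regulation modules), batch effects in clinical cohorts, and
annotation ambiguity (overlapping genes, alternative promoters).  Recovery
rates measured here are upper bounds relative to real-data performance.

## Problem sizes and numerical choices

The default bundle (2,000 genes) runs end-to-end in a few seconds; the
acceptance script uses 5,000 genes for DE calibration and 4,000 null genes
for correlation calibration, sizes at which Monte-Carlo error on a 5% or 1%
rate is small relative to the asserted bands.  Trigamma inversion runs
Newton to a 10⁻¹⁰ relative step; BH adjustment and exact tests come from
statsmodels/scipy.  Degenerate inputs fail loudly: empty annotation files,
all-zero libraries, singular designs, constant expression at the median
split, empty universes and queries all raise with the offending item named.

## Known limitations

* The promoter/distal dichotomy ignores intragenic enhancers closer than
  the flank; such peaks are "promoter" or "intragenic" by precedence.
* The interaction map is taken at face value (cell-type transfer from a
  lymphoblastoid map is the emulated study's own assumption).
* d₀ estimation assumes a single variance prior; no mean–variance trend.
* The correlation screen is marginal (no partial correlations); indirect
  co-expression can produce concordant support for non-targets.
* ORA uses the expressed universe; results are not comparable to tools
  that default to the whole-annotation universe.
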