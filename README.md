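# tfdirect

Direct transcription-factor target calling from integrated ChIP-seq,
knockdown RNA-seq, Capture Hi-C linkage and clinical expression data.

## The problem

Knocking down a transcription factor (TF) and profiling the transcriptome
shows which genes *respond*, but not which respond because the TF binds
them.  `tfdirect` implements the standard integration used to separate
direct from secondary targets in regulatory genomics — here motivated by
ETS-family factors such as FLI1 in germinal-center B-cell (GCB) diffuse
large B-cell lymphoma (DLBCL):

1. **Binding.**  ChIP-seq peaks are classified against a gene annotation
   with precedence promoter > intragenic > intergenic, where a *promoter*
   is the ±3 kb window around each strand-aware TSS.  A peak overlapping a
   promoter window by ≥ 1 bp assigns the TF to that gene; peaks farther
   than 3 kb from every TSS are routed to genes through a Capture Hi-C
   enhancer–promoter interaction map (distal binding).
2. **Response.**  Knockdown-vs-control RNA-seq counts are filtered
   (CPM > 1 in ≥ 3 samples), log2-CPM transformed and tested per gene with
   an empirical-Bayes **moderated t-test** under a joint linear model with a
   cell-line blocking factor.  The per-gene residual variance s²_g (d
   degrees of freedom) is shrunk toward a prior (d₀, s₀²), estimated in
   closed form by moment-matching log s²_g:

       s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),   t_g = logFC_g / (c·s̃_g),

   with p-values on d₀ + d df and Benjamini–Hochberg adjustment.  Calls use
   |logFC| > 0.1 and adj. P < 0.05 (strict).  Because the contrast is
   knockdown − control, *down* after knockdown means *positively regulated*
   by the TF.
3. **Direct targets.**  A gene is a direct target iff it is bound (promoter,
   or distal-only via the interaction map with no promoter peak) **and**
   differentially expressed.  Orthogonal evidence layers — a Pearson
   correlation screen against the TF in clinical specimens (p < 0.01,
   sign-concordant with the regulation direction) and membership in a
   CRISPR-defined essential-gene list — raise a target's evidence tier
   (1 = binding+DE, +1 clinical, +1 essential).

Supporting readouts: the median-dichotomization Fisher test of TF
expression vs GCB/ABC subtype, PWM motif enrichment of peak sequences
against a dinucleotide-shuffled background (Eulerian-path shuffle, exact
dinucleotide preservation), and hypergeometric over-representation analysis
of target sets against GMT collections.

A **synthetic-data generator** (`tfdirect.simulate`) produces a complete,
internally consistent bundle — annotation, peaks, negative-binomial
knockdown counts, interaction map, clinical matrix, essential genes, peak
sequences — with a machine-readable planted truth, so the whole pipeline is
testable offline.

## Worked example

```python
from tfdirect import simulate, de, genome, peaks, chic, clinical, integrate

cfg = simulate.SimConfig(seed=7)          # 2,000 genes, 2 cell lines x 3 reps
simulate.simulate_dataset(cfg, "bundle/")

cm = de.CountMatrix.from_tsv("bundle/counts.tsv", "bundle/samples.tsv")
logcpm, _ = de.filter_and_transform(cm)
res = de.ModeratedTTest(logcpm, cm.samples).fit().call_de(0.1, 0.05)
print(res.summary())
```

```
Moderated t-test results
========================================
genes tested        2000
residual df         9
prior df (d0)       27.2453
prior variance s0^2 0.1273
total df            36.2453
up (neg. regulated) 91
down (pos. regulated) 118
not significant     1791
```

The variance prior borrows ~27 extra degrees of freedom per gene — the
power gain that makes n = 3 replicates per condition workable.  Integrating
the evidence layers:

```python
ann = genome.read_gene_annotation("bundle/annotation.gtf", "gtf")
w = genome.promoter_windows(ann, 3000)
anns = {l: peaks.annotate_peaks(peaks.read_peaks(f"bundle/peaks_{l}.bed", l), ann, w)
        for l in cfg.cell_lines}
_, union, _ = peaks.promoter_gene_sets(anns)
imap = chic.read_interaction_map("bundle/interactions.tsv")
linked = chic.link_distal_peaks([pa for a in anns.values() for pa in a], imap)
distal = chic.distal_only_genes(linked, union)
em = clinical.ExpressionMatrix.from_tsv("bundle/clinical_expression.tsv",
                                        "bundle/clinical_samples.tsv")
corr = clinical.correlation_screen(em, cfg.tf_gene, alpha=0.01, subtype="GCB")
ess = integrate.EssentialGeneList.from_tsv("bundle/essential_genes.tsv")
print(integrate.TargetNetwork(res, union, distal, corr, ess).fit().summary())
```

```
Direct-target integration
========================================
genes tested                 2000
direct targets               95
  positive, promoter-bound   40
  negative, promoter-bound   35
  positive, distal-only      10
  negative, distal-only      10
clinically supported (+/-)   30/27
essential (+/-)              15/0
tier counts 1/2/3            33/52/10
```

The bundle planted 40 + 40 promoter and 10 + 10 distal-only direct targets;
95 of the 100 are recovered (the misses are DE false negatives), none of
the 100 planted *indirect* responders is called direct, and the distal-only
set contains no promoter-bound gene by construction of the set difference.

The same stages are available from the shell:

```bash
tfdirect simulate --seed 7 --out bundle/
tfdirect run --config pipeline.yaml --out out/      # all stages + summary.json
tfdirect peaks annotate --annotation bundle/annotation.gtf \
    --bed bundle/peaks_VAL.bed --flank 3000 --out peaks.tsv
tfdirect de run --counts bundle/counts.tsv --samples bundle/samples.tsv \
    --lfc 0.1 --alpha 0.05 --out de.tsv
```

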