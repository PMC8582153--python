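"""Synthetic dataset generator with planted ground truth.

Emulates the statistical structure of the study design offline: a gene
annotation over a few chromosomes, factor ChIP peaks planted in promoters
and enhancers of true target genes plus background peaks, negative-binomial
knockdown counts for two cell lines with three replicates per condition, a
BEDPE-style enhancer-promoter interaction map, a log-scale clinical
expression matrix with GCB/ABC subtype labels and planted factor-target
correlations, an essential-gene list, and peak-region sequences with the
ETS consensus planted in true-target peaks.  Every file is reproducible
byte-for-byte from the seed, and a machine-readable truth table links each
gene to its planted category:

    direct_pos_promoter / direct_neg_promoter : promoter-bound, knockdown
        effect (down / up respectively)
    direct_pos_distal / direct_neg_distal     : enhancer-linked only
    indirect : knockdown effect without any factor binding
    tf       : the knocked-down factor itself
    null     : no planted effect (a subset carries promoter binding without
               regulation, as bound-but-unresponsive genes do in real data)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

ETS_CONSENSUS = "ACAGGAAGT"


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic bundle.

    Defaults mirror the emulated design: two cell lines with three
    knockdown and three control replicates each, a planted knockdown effect
    of one log2 unit, and a planted clinical correlation of 0.6.
    """

    seed: int
    n_genes: int = 2000
    n_chroms: int = 4
    cell_lines: tuple[str, ...] = ("OCI-Ly1", "VAL")
    replicates: int = 3
    n_direct_pos: int = 40
    n_direct_neg: int = 40
    n_distal_pos: int = 10
    n_distal_neg: int = 10
    n_indirect: int = 100
    n_null_bound: int = 200  # null genes with promoter binding, no regulation
    effect_size_log2: float = 1.0
    nb_dispersion: float = 0.05
    baseline_mean: float = 150.0
    background_peak_count: int = 500
    clinical_n_gcb: int = 75
    clinical_n_abc: int = 75
    clinical_target_r: float = 0.6
    clinical_support_fraction: float = 0.6
    essential_fraction_pos: float = 0.3
    essential_null_count: int = 40
    gene_spacing: int = 50_000
    promoter_flank: int = 3000
    tf_gene: str = "TF_FLI1"

    def __post_init__(self) -> None:
        n_special = (
            self.n_direct_pos + self.n_direct_neg + self.n_distal_pos
            + self.n_distal_neg + self.n_indirect + self.n_null_bound + 1
        )
        if n_special > self.n_genes:
            raise ValueError("planted categories exceed n_genes")
        for f in ("n_genes", "n_chroms", "replicates"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class GroundTruth:
    """Planted per-gene truth, consistent with the emitted files."""

    table: pd.DataFrame  # index gene_id; category, planted_logfc, planted_r, essential

    def genes_in(self, *categories: str) -> set[str]:
        return set(self.table.index[self.table["category"].isin(categories)])

    @property
    def direct_positive(self) -> set[str]:
        return self.genes_in("direct_pos_promoter", "direct_pos_distal")

    @property
    def direct_negative(self) -> set[str]:
        return self.genes_in("direct_neg_promoter", "direct_neg_distal")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# gene layout and category assignment


def _build_genes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    rows = []
    for i in range(cfg.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        start = 100_000 + slot * cfg.gene_spacing
        length = int(rng.integers(2_000, 10_000))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{i:05d}"
        end = start + length
        tss = start if strand == "+" else end - 1
        rows.append((gid, chrom, start, end, strand, tss))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])
    return df.set_index("gene_id")


def _assign_categories(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.Series:
    ids = np.array(genes.index)
    order = rng.permutation(len(ids))
    cat = pd.Series("null", index=genes.index, name="category")
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        sel = ids[order[cursor : cursor + n]]
        cursor += n
        return sel

    cat.loc[take(1)] = "tf"
    cat.loc[take(cfg.n_direct_pos)] = "direct_pos_promoter"
    cat.loc[take(cfg.n_direct_neg)] = "direct_neg_promoter"
    cat.loc[take(cfg.n_distal_pos)] = "direct_pos_distal"
    cat.loc[take(cfg.n_distal_neg)] = "direct_neg_distal"
    cat.loc[take(cfg.n_indirect)] = "indirect"
    cat.loc[take(cfg.n_null_bound)] = "null_bound"
    return cat


# ---------------------------------------------------------------------------
# peaks, interactions, sequences


def _plant_peaks(
    cfg: SimConfig, genes: pd.DataFrame, cat: pd.Series, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (peaks table, interaction pairs table)."""
    peak_rows = []  # chrom, start, end, name, cell_line, is_target_peak
    pair_rows = []  # chrom1,s1,e1,chrom2,s2,e2,genes
    counter = 0

    def add_peak(chrom, start, end, line, is_target):
        nonlocal counter
        peak_rows.append((chrom, int(start), int(end), f"peak_{counter:05d}", line, is_target))
        counter += 1

    promoter_cats = {"direct_pos_promoter", "direct_neg_promoter", "null_bound"}
    distal_cats = {"direct_pos_distal", "direct_neg_distal"}

    forbidden = {c: IntervalTree() for c in genes["chrom"].unique()}
    for gid, g in genes.iterrows():
        # background peaks must stay clear of every promoter window (+ margin)
        forbidden[g.chrom].addi(g.tss - cfg.promoter_flank - 700, g.tss + cfg.promoter_flank + 700)

    for gid in genes.index:  # index order is deterministic
        g = genes.loc[gid]
        c = cat.loc[gid]
        if c in promoter_cats:
            # peak overlapping the +/- flank window in >=1 cell line
            lines = [l for l in cfg.cell_lines if rng.random() < 0.7]
            if not lines:
                lines = [cfg.cell_lines[int(rng.integers(len(cfg.cell_lines)))]]
            for line in lines:
                offset = int(rng.integers(-1500, 1500))
                width = int(rng.integers(200, 600))
                start = g.tss + offset - width // 2
                add_peak(g.chrom, max(0, start), max(0, start) + width,
                         line, c != "null_bound")
        elif c in distal_cats:
            # enhancer anchor ~20 kb downstream of the TSS, peak inside it,
            # linked back to the gene's promoter through the interaction map
            anchor_start = g.tss + 20_000
            anchor_end = anchor_start + 600
            width = int(rng.integers(200, 400))
            pstart = anchor_start + 100
            line = cfg.cell_lines[int(rng.integers(len(cfg.cell_lines)))]
            add_peak(g.chrom, pstart, pstart + width, line, True)
            pair_rows.append(
                (g.chrom, anchor_start, anchor_end,
                 g.chrom, g.tss - 1000, g.tss + 1000, gid)
            )
            forbidden[g.chrom].addi(anchor_start - 700, anchor_end + 700)

    # decoy interaction pairs on null genes (enhancers with no peak)
    null_ids = sorted(cat.index[cat == "null"])
    decoys = rng.choice(len(null_ids), size=min(50, len(null_ids)), replace=False)
    for i in sorted(decoys):
        g = genes.loc[null_ids[i]]
        a0 = g.tss + 25_000
        pair_rows.append((g.chrom, a0, a0 + 600, g.chrom, g.tss - 1000, g.tss + 1000,
                          null_ids[i]))
        forbidden[g.chrom].addi(a0 - 700, a0 + 700)

    # background peaks: never in a promoter window or an enhancer anchor;
    # roughly half are drawn inside gene bodies so the context mix resembles
    # real TF peak sets (intragenic vs intergenic)
    chroms = sorted(genes["chrom"].unique())
    span = {c: int(genes.loc[genes["chrom"] == c, "end"].max()) + 50_000 for c in chroms}
    gene_list = list(genes.itertuples())
    placed = 0
    while placed < cfg.background_peak_count:
        width = int(rng.integers(200, 600))
        if rng.random() < 0.5:
            g = gene_list[int(rng.integers(len(gene_list)))]
            if g.end - g.start <= width:
                continue
            chrom = g.chrom
            start = int(rng.integers(g.start, g.end - width))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, span[chrom] - width))
        if forbidden[chrom].overlap(start, start + width):
            continue
        line = cfg.cell_lines[int(rng.integers(len(cfg.cell_lines)))]
        add_peak(chrom, start, start + width, line, False)
        placed += 1

    peaks = pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "name", "cell_line", "is_target_peak"]
    )
    pairs = pd.DataFrame(
        pair_rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "genes"]
    )
    return peaks, pairs


def _peak_sequences(
    cfg: SimConfig, peaks: pd.DataFrame, rng: np.random.Generator
) -> list[tuple[str, str]]:
    bases = np.array(list("ACGT"))
    seqs = []
    for row in peaks.itertuples():
        length = min(row.end - row.start, 400)
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        if row.is_target_peak:
            pos = int(rng.integers(0, length - len(ETS_CONSENSUS)))
            seq = seq[:pos] + ETS_CONSENSUS + seq[pos + len(ETS_CONSENSUS):]
        seqs.append((row.name, seq))
    return seqs


# ---------------------------------------------------------------------------
# counts and clinical matrix


def simulate_counts(
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial knockdown counts (genes x samples) + sample sheet.

    Gene baselines are log-normal (planted targets floored at a moderately
    expressed level so regulation is observable); knockdown samples of
    positively regulated targets are scaled by ``2**-effect``, negatively
    regulated by ``2**+effect``; the factor itself is knocked down hard.
    Library sizes are jittered +/-20%.  ``nb_dispersion == 0`` degenerates
    to Poisson sampling.
    """
    genes = truth.table.index
    n_g = len(genes)
    base = rng.lognormal(mean=np.log(cfg.baseline_mean), sigma=1.2, size=n_g)
    planted = truth.table["planted_logfc"].to_numpy()
    is_target = planted != 0.0
    base = np.where(is_target, np.maximum(base, 50.0), base)

    samples = []
    for line in cfg.cell_lines:
        for cond in ("control", "knockdown"):
            for rep in range(1, cfg.replicates + 1):
                samples.append((f"{line}.{cond}.{rep}", line, cond, rep))
    sheet = pd.DataFrame(
        samples, columns=["sample", "cell_line", "condition", "replicate"]
    ).set_index("sample")

    # mild per-gene cell-line effect so the blocking covariate has a job
    line_fc = {
        line: (np.zeros(n_g) if i == 0 else rng.normal(0.0, 0.2, size=n_g))
        for i, line in enumerate(cfg.cell_lines)
    }
    counts = np.zeros((n_g, len(sheet)), dtype=np.int64)
    for j, (sname, row) in enumerate(sheet.iterrows()):
        mu = base * 2.0 ** line_fc[row.cell_line]
        if row.condition == "knockdown":
            mu = mu * 2.0**planted
        mu = mu * rng.uniform(0.8, 1.2)  # library-size jitter
        if cfg.nb_dispersion > 0:
            lam = rng.gamma(shape=1.0 / cfg.nb_dispersion,
                            scale=mu * cfg.nb_dispersion)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    return pd.DataFrame(counts, index=genes, columns=sheet.index), sheet


def simulate_clinical_matrix(
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-scale clinical expression with subtype labels and planted r.

    The factor row is normal with a higher mean in GCB than ABC samples
    (so the median-dichotomization test has planted signal); each clinically
    supported target is built from the factor's standardized latent variable
    at the planted correlation, sign matching its regulation; all other
    genes are independent.
    """
    n = cfg.clinical_n_gcb + cfg.clinical_n_abc
    subtypes = pd.Series(
        ["GCB"] * cfg.clinical_n_gcb + ["ABC"] * cfg.clinical_n_abc,
        index=[f"S{i:03d}" for i in range(n)],
        name="subtype",
    )
    z = rng.normal(size=n)  # latent factor variation shared with targets
    tf_mean = np.where(subtypes.to_numpy() == "GCB", 6.0, 5.2)
    tf_expr = tf_mean + z

    genes = truth.table.index
    mu_g = rng.normal(5.0, 1.0, size=len(genes))
    r = truth.table["planted_r"].to_numpy()
    eps = rng.normal(size=(len(genes), n))
    X = mu_g[:, None] + r[:, None] * z[None, :] + np.sqrt(1.0 - r**2)[:, None] * eps
    X[genes.get_loc(cfg.tf_gene), :] = tf_expr
    values = pd.DataFrame(np.round(X, 6), index=genes, columns=subtypes.index)
    return values, subtypes


# ---------------------------------------------------------------------------
# bundle assembly


def _build_truth(cfg: SimConfig, cat: pd.Series, rng: np.random.Generator) -> GroundTruth:
    eff = cfg.effect_size_log2
    logfc = pd.Series(0.0, index=cat.index)
    logfc[cat == "direct_pos_promoter"] = -eff
    logfc[cat == "direct_pos_distal"] = -eff
    logfc[cat == "direct_neg_promoter"] = eff
    logfc[cat == "direct_neg_distal"] = eff
    logfc[cat == "tf"] = -2.0
    ind = sorted(cat.index[cat == "indirect"])
    signs = rng.choice([-1.0, 1.0], size=len(ind))
    logfc[ind] = signs * eff

    planted_r = pd.Series(0.0, index=cat.index)
    for c, sign in (
        ("direct_pos_promoter", 1.0), ("direct_pos_distal", 1.0),
        ("direct_neg_promoter", -1.0), ("direct_neg_distal", -1.0),
    ):
        members = sorted(cat.index[cat == c])
        k = int(round(cfg.clinical_support_fraction * len(members)))
        chosen = rng.choice(len(members), size=k, replace=False)
        for i in sorted(chosen):
            planted_r[members[i]] = sign * cfg.clinical_target_r

    essential = pd.Series(False, index=cat.index)
    pos = sorted(cat.index[cat.isin(["direct_pos_promoter", "direct_pos_distal"])])
    k = int(round(cfg.essential_fraction_pos * len(pos)))
    for i in sorted(rng.choice(len(pos), size=k, replace=False)):
        essential[pos[i]] = True
    nulls = sorted(cat.index[cat == "null"])
    for i in sorted(rng.choice(len(nulls), size=min(cfg.essential_null_count, len(nulls)),
                               replace=False)):
        essential[nulls[i]] = True

    cat_out = cat.replace({"null_bound": "null"})
    table = pd.DataFrame(
        {"category": cat_out, "planted_logfc": logfc, "planted_r": planted_r,
         "essential": essential}
    )
    return GroundTruth(table)


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> GroundTruth:
    """Write the complete synthetic bundle to ``outdir``; return the truth.

    Files: annotation.gtf, annotation.bed12, peaks_<line>.bed per cell line,
    counts.tsv, samples.tsv, interactions.tsv, clinical_expression.tsv,
    clinical_samples.tsv, essential_genes.tsv, peak_sequences.fa, truth.tsv.
    Deterministic byte-for-byte given ``cfg.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes = _build_genes(cfg, rng)
    cat = _assign_categories(cfg, genes, rng)
    # rename the factor gene so downstream config can refer to it by name
    tf_old = cat.index[cat == "tf"][0]
    genes = genes.rename(index={tf_old: cfg.tf_gene})
    cat = cat.rename(index={tf_old: cfg.tf_gene})

    truth = _build_truth(cfg, cat, rng)
    peaks, pairs = _plant_peaks(cfg, genes, cat, rng)
    seqs = _peak_sequences(cfg, peaks, rng)
    counts, sheet = simulate_counts(truth, cfg, rng)
    clin_values, clin_subtypes = simulate_clinical_matrix(truth, cfg, rng)

    # --- annotation
    with open(outdir / "annotation.gtf", "w") as fh:
        for gid, g in genes.iterrows():
            attrs = f'gene_id "{gid}"; gene_name "{gid}"; gene_type "protein_coding";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    with open(outdir / "annotation.bed12", "w") as fh:
        for gid, g in genes.iterrows():
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{gid}\t0\t{g.strand}\t{g.start}\t{g.end}"
                f"\t0,0,0\t1\t{g.end - g.start}\t0\n"
            )

    # --- peaks per cell line
    for line in cfg.cell_lines:
        sub = peaks[peaks["cell_line"] == line]
        safe = line.replace("/", "_")
        with open(outdir / f"peaks_{safe}.bed", "w") as fh:
            for row in sub.itertuples():
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\n")

    # --- counts + samples
    counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample")

    # --- interactions
    with open(outdir / "interactions.tsv", "w") as fh:
        for row in pairs.itertuples(index=False):
            fh.write("\t".join(map(str, row)) + "\n")

    # --- clinical
    clin_values.to_csv(outdir / "clinical_expression.tsv", sep="\t", index_label="gene_id")
    clin_subtypes.to_frame().to_csv(outdir / "clinical_samples.tsv", sep="\t",
                                    index_label="sample")

    # --- essential genes
    ess = sorted(truth.table.index[truth.table["essential"]])
    with open(outdir / "essential_genes.tsv", "w") as fh:
        fh.write("gene_id\n")
        for g in ess:
            fh.write(g + "\n")

    # --- peak sequences
    with open(outdir / "peak_sequences.fa", "w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n{seq}\n")

    truth.to_tsv(outdir / "truth.tsv")
    return truth


def default_pipeline_config(cfg: SimConfig, outdir: str | Path, seed: int = 0) -> dict:
    """Pipeline config dict pointing at a simulated bundle."""
    outdir = Path(outdir)
    return {
        "annotation": str(outdir / "annotation.gtf"),
        "annotation_format": "gtf",
        "peaks": {
            line: str(outdir / f"peaks_{line.replace('/', '_')}.bed")
            for line in cfg.cell_lines
        },
        "counts": str(outdir / "counts.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "interactions": str(outdir / "interactions.tsv"),
        "clinical_expression": str(outdir / "clinical_expression.tsv"),
        "clinical_samples": str(outdir / "clinical_samples.tsv"),
        "tf_gene": cfg.tf_gene,
        "correlation_subtype": "GCB",
        "essential_genes": str(outdir / "essential_genes.tsv"),
        "peak_sequences": str(outdir / "peak_sequences.fa"),
        "seed": seed,
    }


def validate_bundle(outdir: str | Path, cfg: SimConfig) -> None:
    """Re-read a bundle and assert the ground-truth invariants.

    Checks that every promoter-category target has >= 1 peak overlapping its
    promoter window, every distal target has an enhancer-linked distal peak
    and no promoter peak, and that category counts match the configuration.
    Raises AssertionError on any violation.
    """
    from tfdirect import chic as chic_mod
    from tfdirect import genome as genome_mod
    from tfdirect import peaks as peaks_mod

    outdir = Path(outdir)
    truth = GroundTruth.from_tsv(outdir / "truth.tsv")
    ann = genome_mod.read_gene_annotation(outdir / "annotation.gtf", "gtf")
    windows = genome_mod.promoter_windows(ann, flank=cfg.promoter_flank)
    anns_by_line = {}
    for line in cfg.cell_lines:
        pk = peaks_mod.read_peaks(outdir / f"peaks_{line.replace('/', '_')}.bed", line)
        anns_by_line[line] = peaks_mod.annotate_peaks(pk, ann, windows)
    _, union, _ = peaks_mod.promoter_gene_sets(anns_by_line)

    cats = truth.table["category"]
    promoter_targets = truth.genes_in("direct_pos_promoter", "direct_neg_promoter")
    assert promoter_targets <= union, "promoter target missing its promoter peak"

    imap = chic_mod.read_interaction_map(outdir / "interactions.tsv")
    all_ann = [pa for anns in anns_by_line.values() for pa in anns]
    linked = chic_mod.link_distal_peaks(all_ann, imap, flank=cfg.promoter_flank)
    distal_targets = truth.genes_in("direct_pos_distal", "direct_neg_distal")
    assert distal_targets <= set(linked), "distal target missing enhancer-linked peak"
    assert not (distal_targets & union), "distal target has a promoter peak"

    expect = {
        "direct_pos_promoter": cfg.n_direct_pos,
        "direct_neg_promoter": cfg.n_direct_neg,
        "direct_pos_distal": cfg.n_distal_pos,
        "direct_neg_distal": cfg.n_distal_neg,
        "indirect": cfg.n_indirect,
        "tf": 1,
    }
    vc = cats.value_counts()
    for c, n in expect.items():
        assert vc.get(c, 0) == n, f"category {c}: expected {n}, got {vc.get(c, 0)}"
    # indirect genes never carry binding evidence
    indirect = truth.genes_in("indirect")
    assert not (indirect & union), "indirect gene carries a promoter peak"
    assert not (indirect & set(linked)), "indirect gene is enhancer-linked"
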