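"""Tiered direct-target calling: binding x knockdown DE x clinical x essentiality.

A gene is a *direct* target when it is bound by the factor (a peak in its
promoter window, or a distal peak routed to it through the enhancer-promoter
interaction map with no promoter peak) and differentially expressed after
factor knockdown.  The knockdown sign convention maps DE calls to regulation:
a gene *down* after knockdown is positively regulated by the factor, a gene
*up* is negatively regulated.  Clinical support (significant expression
correlation with the factor, sign-concordant with the regulation) and
membership in an essential-gene list are orthogonal evidence layers; the
tier integer counts accumulated evidence (1 = binding + DE, +1 clinical,
+1 essential) while the two flags stay independently reported.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from tfdirect import chic, clinical, de, genome, motif, peaks

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EssentialGeneList:
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("essential-gene list is empty")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EssentialGeneList":
        genes = set()
        with open(path) as fh:
            for line in fh:
                g = line.strip().split("\t")[0]
                if g and g.lower() != "gene_id":
                    genes.add(g)
        return cls(frozenset(genes))


@dataclass
class TargetCall:
    """Evidence bundle for one gene."""

    gene_id: str
    binding: str  # promoter | distal_only | none
    de_call: str  # up | down | ns
    clinical_support: bool = False
    essential: bool = False

    def __post_init__(self) -> None:
        if self.binding not in ("promoter", "distal_only", "none"):
            raise ValueError(f"bad binding {self.binding!r}")
        if self.de_call not in ("up", "down", "ns"):
            raise ValueError(f"bad de_call {self.de_call!r}")

    @property
    def regulation(self) -> str:
        # down after knockdown => the factor was sustaining it => positive
        return {"down": "positive", "up": "negative", "ns": "none"}[self.de_call]

    @property
    def is_direct(self) -> bool:
        return self.binding != "none" and self.de_call != "ns"

    @property
    def tier(self) -> int:
        if not self.is_direct:
            return 0
        return 1 + int(self.clinical_support) + int(self.essential)


def call_direct_targets(
    de_results: de.DEResults,
    promoter_gene_union: set[str],
    distal_only: set[str],
) -> list[TargetCall]:
    """Combine binding evidence with DE calls into direct-target calls.

    Only DE-significant genes with binding are direct; promoter binding
    takes precedence over distal-only linkage (the distal set is expected
    to already exclude promoter-bound genes, re-asserted here).
    """
    overlap = distal_only & promoter_gene_union
    if overlap:
        raise ValueError(
            f"distal_only set contains promoter-bound genes: {sorted(overlap)[:5]}"
        )
    calls = de_results.calls
    out = []
    for gene_id, call in calls.items():
        if gene_id in promoter_gene_union:
            binding = "promoter"
        elif gene_id in distal_only:
            binding = "distal_only"
        else:
            binding = "none"
        out.append(TargetCall(gene_id=gene_id, binding=binding, de_call=call))
    return out


def tier_targets(
    targets: Sequence[TargetCall],
    correlations: Sequence[clinical.CorrelationResult],
    essentials: EssentialGeneList | None = None,
    *,
    require_concordance: bool = True,
) -> list[TargetCall]:
    """Attach clinical-support and essentiality flags to target calls.

    Clinical support requires a significant correlation whose sign is
    concordant with the regulation direction (positive regulation <-> r > 0)
    unless ``require_concordance`` is disabled.
    """
    corr_by_gene = {c.gene_id: c for c in correlations}
    ess = essentials.genes if essentials else frozenset()
    out = []
    for t in targets:
        c = corr_by_gene.get(t.gene_id)
        support = False
        if c is not None and t.regulation != "none":
            if require_concordance:
                support = (t.regulation == "positive") == (c.r > 0)
            else:
                support = True
        out.append(
            TargetCall(
                gene_id=t.gene_id,
                binding=t.binding,
                de_call=t.de_call,
                clinical_support=support,
                essential=t.gene_id in ess,
            )
        )
    return out


def targets_to_frame(targets: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in targets],
            "binding": [t.binding for t in targets],
            "de_call": [t.de_call for t in targets],
            "regulation": [t.regulation for t in targets],
            "clinical_support": [t.clinical_support for t in targets],
            "essential": [t.essential for t in targets],
            "tier": [t.tier for t in targets],
        }
    ).set_index("gene_id")


def summarize_targets(targets: Sequence[TargetCall]) -> dict:
    """Intersection counts mirroring the integration table.

    Every reported count is a recomputed set size (Venn identities hold by
    construction).
    """
    direct = [t for t in targets if t.is_direct]

    def count(binding=None, regulation=None, clinical_flag=None, essential_flag=None):
        sel = direct
        if binding is not None:
            sel = [t for t in sel if t.binding == binding]
        if regulation is not None:
            sel = [t for t in sel if t.regulation == regulation]
        if clinical_flag is not None:
            sel = [t for t in sel if t.clinical_support == clinical_flag]
        if essential_flag is not None:
            sel = [t for t in sel if t.essential == essential_flag]
        return len(sel)

    return {
        "n_genes_tested": len(targets),
        "n_direct": len(direct),
        "direct_positive_promoter": count("promoter", "positive"),
        "direct_negative_promoter": count("promoter", "negative"),
        "direct_positive_distal": count("distal_only", "positive"),
        "direct_negative_distal": count("distal_only", "negative"),
        "clinically_supported_positive": count(regulation="positive", clinical_flag=True),
        "clinically_supported_negative": count(regulation="negative", clinical_flag=True),
        "essential_positive": count(regulation="positive", essential_flag=True),
        "essential_negative": count(regulation="negative", essential_flag=True),
        "tier_counts": {
            str(k): sum(t.tier == k for t in direct) for k in (1, 2, 3)
        },
    }


class TargetNetwork:
    """Model object bundling all evidence layers for direct-target inference.

    Built from the evidence inputs (DE results, promoter-bound gene union,
    distal-only gene set, clinical correlations, essential genes); ``fit()``
    performs the integration and returns a :class:`TargetResults`.
    """

    def __init__(
        self,
        de_results: de.DEResults,
        promoter_gene_union: set[str],
        distal_only: set[str],
        correlations: Sequence[clinical.CorrelationResult] = (),
        essentials: EssentialGeneList | None = None,
    ):
        self.de_results = de_results
        self.promoter_gene_union = promoter_gene_union
        self.distal_only = distal_only
        self.correlations = correlations
        self.essentials = essentials

    def fit(self, *, require_concordance: bool = True) -> "TargetResults":
        targets = call_direct_targets(
            self.de_results, self.promoter_gene_union, self.distal_only
        )
        targets = tier_targets(
            targets,
            self.correlations,
            self.essentials,
            require_concordance=require_concordance,
        )
        return TargetResults(targets=targets, summary_counts=summarize_targets(targets))


@dataclass
class TargetResults:
    targets: list[TargetCall]
    summary_counts: dict

    @property
    def direct_targets(self) -> list[TargetCall]:
        return [t for t in self.targets if t.is_direct]

    def frame(self) -> pd.DataFrame:
        return targets_to_frame(self.targets)

    def summary(self) -> str:
        s = self.summary_counts
        lines = [
            "Direct-target integration",
            "=" * 40,
            f"genes tested                 {s['n_genes_tested']}",
            f"direct targets               {s['n_direct']}",
            f"  positive, promoter-bound   {s['direct_positive_promoter']}",
            f"  negative, promoter-bound   {s['direct_negative_promoter']}",
            f"  positive, distal-only      {s['direct_positive_distal']}",
            f"  negative, distal-only      {s['direct_negative_distal']}",
            f"clinically supported (+/-)   {s['clinically_supported_positive']}"
            f"/{s['clinically_supported_negative']}",
            f"essential (+/-)              {s['essential_positive']}"
            f"/{s['essential_negative']}",
            f"tier counts 1/2/3            "
            + "/".join(str(s["tier_counts"][k]) for k in ("1", "2", "3")),
        ]
        return "\n".join(lines)


DEFAULT_THRESHOLDS = {
    "flank": 3000,
    "min_cpm": 1.0,
    "min_samples": 3,
    "lfc": 0.1,
    "alpha_de": 0.05,
    "alpha_corr": 0.01,
}


class PipelineConfigError(ValueError):
    pass


def run_pipeline(config: Mapping | str | Path, outdir: str | Path) -> dict:
    """Execute all stages in dependency order and write the report bundle.

    ``config`` is a mapping (or a YAML path) naming the inputs::

        annotation: path (GTF)
        annotation_format: gtf | bed12
        peaks: {cell_line: bed_path, ...}
        counts: tsv path
        samples: tsv path
        interactions: bedpe+genes path     (optional; enables distal stage)
        clinical_expression: tsv path      (optional)
        clinical_samples: tsv path         (optional)
        tf_gene: gene_id                   (required with clinical matrix)
        essential_genes: tsv path          (optional)
        peak_sequences: fasta path         (optional; motif enrichment)
        thresholds: {flank, min_cpm, min_samples, lfc, alpha_de, alpha_corr}
        seed: int

    Writes intermediate TSVs, ``summary.json`` and ``pipeline.log`` under
    ``outdir`` and returns the summary dict.  Configuration is validated
    before any compute; any stage error aborts with the stage name.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- validate up front, before any compute
    for key in ("annotation", "peaks", "counts", "samples"):
        if key not in config:
            raise PipelineConfigError(f"missing required config key {key!r}")
    paths = [config["annotation"], config["counts"], config["samples"]]
    paths += list(config["peaks"].values())
    for opt in ("interactions", "clinical_expression", "clinical_samples",
                "essential_genes", "peak_sequences"):
        if config.get(opt):
            paths.append(config[opt])
    for p in paths:
        if not Path(p).exists():
            raise PipelineConfigError(f"input path does not exist: {p}")
    if config.get("clinical_expression") and not config.get("tf_gene"):
        raise PipelineConfigError("tf_gene required when a clinical matrix is given")
    th = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    seed = int(config.get("seed", 0))

    log_lines = [f"tfdirect pipeline, seed={seed}, thresholds={json.dumps(th, sort_keys=True)}"]
    t0 = time.time()
    stage = "annotation"
    try:
        ann = genome.read_gene_annotation(
            config["annotation"], config.get("annotation_format", "gtf")
        )
        windows = genome.promoter_windows(ann, flank=int(th["flank"]))
        log_lines.append(f"annotation: {len(ann)} genes")

        stage = "peaks"
        anns_by_line = {}
        for line, bed in sorted(config["peaks"].items()):
            pk = peaks.read_peaks(bed, cell_line=line)
            anns_by_line[line] = peaks.annotate_peaks(pk, ann, windows)
            log_lines.append(f"peaks[{line}]: {len(pk)}")
        all_ann = [pa for anns in anns_by_line.values() for pa in anns]
        peaks.annotations_to_frame(all_ann).to_csv(
            outdir / "peak_annotations.tsv", sep="\t", index=False
        )
        per_line, promoter_union, promoter_common = peaks.promoter_gene_sets(anns_by_line)
        ctx = peaks.context_distribution(all_ann)

        stage = "differential_expression"
        cm = de.CountMatrix.from_tsv(config["counts"], config["samples"])
        logcpm, _ = de.filter_and_transform(
            cm, min_cpm=float(th["min_cpm"]), min_samples=int(th["min_samples"])
        )
        res = de.ModeratedTTest(logcpm, cm.samples).fit()
        res = res.call_de(lfc_threshold=float(th["lfc"]), alpha=float(th["alpha_de"]))
        res.to_tsv(outdir / "de_results.tsv")
        log_lines.append(
            f"DE: {len(res.table)} genes tested, d0={res.params.d0:.3g}"
        )

        stage = "chic_linkage"
        distal: set[str] = set()
        if config.get("interactions"):
            imap = chic.read_interaction_map(config["interactions"])
            linked = chic.link_distal_peaks(all_ann, imap, flank=int(th["flank"]))
            distal = chic.distal_only_genes(linked, promoter_union)
            pd.Series(sorted(distal), name="gene_id").to_csv(
                outdir / "distal_only_genes.tsv", sep="\t", index=False
            )
            log_lines.append(f"C-HiC: {len(linked)} linked, {len(distal)} distal-only")

        stage = "clinical_support"
        correlations: list[clinical.CorrelationResult] = []
        contingency = None
        if config.get("clinical_expression"):
            em = clinical.ExpressionMatrix.from_tsv(
                config["clinical_expression"], config["clinical_samples"]
            )
            correlations = clinical.correlation_screen(
                em, config["tf_gene"], alpha=float(th["alpha_corr"]),
                subtype=config.get("correlation_subtype"),
            )
            clinical.correlations_to_frame(correlations).to_csv(
                outdir / "clinical_correlations.tsv", sep="\t"
            )
            contingency = clinical.dichotomize_and_test(em, config["tf_gene"])
            log_lines.append(
                f"clinical: {len(correlations)} correlated, "
                f"dichotomization p={contingency.p:.3g}"
            )

        stage = "essential_genes"
        essentials = None
        if config.get("essential_genes"):
            essentials = EssentialGeneList.from_tsv(config["essential_genes"])

        stage = "target_integration"
        model = TargetNetwork(res, promoter_union, distal, correlations, essentials)
        results = model.fit(
            require_concordance=bool(config.get("require_concordance", True))
        )
        results.frame().to_csv(outdir / "target_calls.tsv", sep="\t")

        stage = "motif_enrichment"
        motif_report = None
        if config.get("peak_sequences"):
            seqs = motif.read_fasta(config["peak_sequences"])
            fold, pval = motif.enrichment_test(seqs, motif.ets_core_pwm(), seed=seed)
            motif_report = {"fold": fold, "p": pval, "n_sequences": len(seqs)}
            log_lines.append(f"motif: fold={fold:.3g}, p={pval:.3g}")
    except PipelineConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "seed": seed,
        "thresholds": th,
        "n_genes_annotation": len(ann),
        "promoter_bound": {
            "per_cell_line": {k: len(v) for k, v in sorted(per_line.items())},
            "union": len(promoter_union),
            "common": len(promoter_common),
        },
        "peak_context_fractions": {k: round(v, 6) for k, v in ctx.items()},
        "de": {
            "n_tested": int(len(res.table)),
            "d0": float(res.params.d0) if np.isfinite(res.params.d0) else None,
            "n_up": int((res.calls == "up").sum()),
            "n_down": int((res.calls == "down").sum()),
        },
        "targets": results.summary_counts,
    }
    if contingency is not None:
        summary["dichotomization"] = {
            "table": contingency.table.tolist(),
            "odds_ratio": contingency.odds_ratio,
            "p": contingency.p,
        }
    if motif_report is not None:
        summary["motif_enrichment"] = motif_report
    log_lines.append(f"done in {time.time() - t0:.1f}s")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "pipeline.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary
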