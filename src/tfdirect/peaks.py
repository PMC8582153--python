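"""ChIP-seq peak loading and genomic-context annotation.

Each peak is classified with precedence promoter > intragenic > intergenic:
a peak overlapping any promoter window by >= 1 bp is a promoter peak and is
assigned to every gene whose window it touches; otherwise overlap with any
gene body makes it intragenic; otherwise intergenic.  Nearest TSS and the
signed midpoint-to-TSS distance are recorded for every peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from tfdirect.genome import GenomeAnnotation, PromoterWindow

CONTEXTS = ("promoter", "intragenic", "intergenic")


class PeakParseError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    score: float = 0.0
    cell_line: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"inverted/empty interval [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    context: str  # promoter | intragenic | intergenic
    nearest_gene: str | None
    tss_distance: int | None  # signed, midpoint relative to TSS strand
    promoter_genes: frozenset[str]


def read_peaks(path: str | Path, cell_line: str) -> list[Peak]:
    """Read a BED3+ peak file; column 4 is the name, column 5 the score.

    Zero-length or inverted intervals and non-numeric coordinates raise
    PeakParseError with the offending line number.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 3:
                    raise ValueError(f"expected >=3 BED columns, got {len(fields)}")
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                peaks.append(
                    Peak(fields[0], start, end, score=score, cell_line=cell_line, name=name)
                )
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def _window_trees(windows: Sequence[PromoterWindow]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        if w.start < w.end:
            trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, w.gene_id)
    return trees


def annotate_peaks(
    peaks: Iterable[Peak],
    annotation: GenomeAnnotation,
    windows: Sequence[PromoterWindow],
    *,
    nearest_only: bool = False,
) -> list[PeakAnnotation]:
    """Classify each peak's genomic context against the annotation.

    Precedence: promoter (>= 1 bp overlap with any promoter window) >
    intragenic (overlap with any gene body) > intergenic.  With
    ``nearest_only`` a promoter peak keeps only the window gene whose TSS is
    nearest to the peak midpoint.  Peaks on chromosomes absent from the
    annotation are intergenic with null nearest fields (a warning is issued
    once per chromosome).
    """
    trees = _window_trees(windows)
    warned: set[str] = set()
    out: list[PeakAnnotation] = []
    for p in peaks:
        if p.chrom not in annotation.chroms:
            if p.chrom not in warned:
                warnings.warn(f"peak chromosome {p.chrom!r} absent from annotation")
                warned.add(p.chrom)
            out.append(PeakAnnotation(p, "intergenic", None, None, frozenset()))
            continue
        tree = trees.get(p.chrom)
        promoter_genes = (
            frozenset(iv.data for iv in tree.overlap(p.start, p.end)) if tree else frozenset()
        )
        near = annotation.nearest_tss(p.chrom, p.midpoint)
        assert near is not None
        nearest_gene, dist = near
        # sign the distance relative to the TSS strand: positive = downstream
        if annotation[nearest_gene].strand == "-":
            dist = -dist
        if promoter_genes:
            if nearest_only:
                keep = min(
                    promoter_genes,
                    key=lambda gid: (abs(p.midpoint - annotation[gid].tss), gid),
                )
                promoter_genes = frozenset({keep})
            out.append(PeakAnnotation(p, "promoter", nearest_gene, dist, promoter_genes))
        elif annotation.overlapping_genes(p.chrom, p.start, p.end):
            out.append(PeakAnnotation(p, "intragenic", nearest_gene, dist, frozenset()))
        else:
            out.append(PeakAnnotation(p, "intergenic", nearest_gene, dist, frozenset()))
    return out


def promoter_gene_sets(
    annotations_by_line: Mapping[str, Sequence[PeakAnnotation]],
) -> tuple[dict[str, set[str]], set[str], set[str]]:
    """Per-cell-line promoter-bound gene sets, their union and intersection.

    Mirrors the deduplication step in which transcripts bearing one or more
    peaks in their promoter are pooled across cell lines and the common core
    is counted.
    """
    if not annotations_by_line:
        raise ValueError("need at least one cell line")
    per_line = {
        line: set().union(*(pa.promoter_genes for pa in anns), set())
        for line, anns in annotations_by_line.items()
    }
    union: set[str] = set().union(*per_line.values())
    common: set[str] = set.intersection(*per_line.values()) if per_line else set()
    return per_line, union, common


def context_distribution(annotations: Sequence[PeakAnnotation]) -> dict[str, float]:
    """Fraction of peaks in each genomic context (sums to 1)."""
    if not annotations:
        raise ValueError("no peak annotations")
    n = len(annotations)
    return {c: sum(pa.context == c for pa in annotations) / n for c in CONTEXTS}


def annotations_to_frame(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    """Tabular view: one row per peak with context columns."""
    return pd.DataFrame(
        {
            "chrom": [pa.peak.chrom for pa in annotations],
            "start": [pa.peak.start for pa in annotations],
            "end": [pa.peak.end for pa in annotations],
            "name": [pa.peak.name for pa in annotations],
            "score": [pa.peak.score for pa in annotations],
            "cell_line": [pa.peak.cell_line for pa in annotations],
            "context": [pa.context for pa in annotations],
            "nearest_gene": [pa.nearest_gene for pa in annotations],
            "tss_distance": [pa.tss_distance for pa in annotations],
            "promoter_genes": [",".join(sorted(pa.promoter_genes)) for pa in annotations],
        }
    )
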