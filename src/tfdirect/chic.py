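"""Enhancer-promoter interaction maps: routing distal peaks to genes.

Peaks farther than the promoter flank from every TSS are matched against
enhancer anchors of a Capture Hi-C-style interaction map; an overlapping
anchor contributes the gene labels of its interacting promoter anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from tfdirect.peaks import PeakAnnotation


class InteractionParseError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionPair:
    """One enhancer anchor linked to one gene-labelled promoter anchor."""

    enhancer_anchor: tuple[str, int, int]
    promoter_anchor: tuple[str, int, int]
    target_genes: frozenset[str]

    def __post_init__(self) -> None:
        for chrom, start, end in (self.enhancer_anchor, self.promoter_anchor):
            if start >= end:
                raise ValueError(f"inverted anchor {chrom}:{start}-{end}")
        if not self.target_genes:
            raise ValueError("target_genes must be nonempty")


class InteractionMap:
    """Interaction pairs with an interval index over enhancer anchors."""

    def __init__(self, pairs: Iterable[InteractionPair]):
        self.pairs: list[InteractionPair] = list(pairs)
        self._trees: dict[str, IntervalTree] = {}
        for i, pair in enumerate(self.pairs):
            chrom, start, end = pair.enhancer_anchor
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, i)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def overlapping_pairs(self, chrom: str, start: int, end: int) -> list[InteractionPair]:
        """Pairs whose enhancer anchor overlaps [start, end) by >= 1 bp."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.pairs[iv.data] for iv in tree.overlap(start, end)]


def read_interaction_map(path: str | Path) -> InteractionMap:
    """Read a BEDPE-like TSV: chrom1 start1 end1 chrom2 start2 end2 genes.

    The first anchor is the enhancer side, the second the promoter side;
    the genes column is a comma-separated list annotated to the promoter
    anchor.  Rows with an empty gene field are rejected with a warning;
    inverted anchors raise a record-level error.
    """
    path = Path(path)
    pairs: list[InteractionPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise InteractionParseError(
                    f"{path}:{lineno}: expected >=7 columns (BEDPE + genes), got {len(fields)}"
                )
            genes = frozenset(g.strip() for g in fields[6].split(",") if g.strip())
            if not genes:
                warnings.warn(f"{path}:{lineno}: empty gene field, row skipped")
                continue
            try:
                pairs.append(
                    InteractionPair(
                        enhancer_anchor=(fields[0], int(fields[1]), int(fields[2])),
                        promoter_anchor=(fields[3], int(fields[4]), int(fields[5])),
                        target_genes=genes,
                    )
                )
            except ValueError as exc:
                raise InteractionParseError(f"{path}:{lineno}: {exc}") from exc
    return InteractionMap(pairs)


def write_interaction_map(imap: InteractionMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pair in imap:
            e, p = pair.enhancer_anchor, pair.promoter_anchor
            fh.write(
                f"{e[0]}\t{e[1]}\t{e[2]}\t{p[0]}\t{p[1]}\t{p[2]}\t"
                + ",".join(sorted(pair.target_genes))
                + "\n"
            )


def link_distal_peaks(
    peak_annotations: Sequence[PeakAnnotation],
    imap: InteractionMap,
    flank: int = 3000,
) -> dict[str, list[PeakAnnotation]]:
    """Assign distal peaks to genes via overlapping enhancer anchors.

    A peak is eligible when its |TSS distance| exceeds ``flank`` (i.e. it
    lies outside every promoter window).  An eligible peak overlapping an
    enhancer anchor by >= 1 bp contributes all of that pair's target genes.
    Returns gene_id -> supporting peak annotations (union over peaks).
    """
    linked: dict[str, list[PeakAnnotation]] = {}
    for pa in peak_annotations:
        if pa.tss_distance is None or abs(pa.tss_distance) <= flank:
            continue
        genes: set[str] = set()
        for pair in imap.overlapping_pairs(pa.peak.chrom, pa.peak.start, pa.peak.end):
            genes |= pair.target_genes
        for g in genes:
            linked.setdefault(g, []).append(pa)
    return linked


def distal_only_genes(
    linked_genes: Mapping[str, Sequence[PeakAnnotation]] | Iterable[str],
    promoter_gene_union: set[str],
) -> set[str]:
    """Enhancer-linked genes with no promoter peak: set difference."""
    genes = set(linked_genes)
    return genes - promoter_gene_union
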