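"""Gene annotation model: strand-aware TSS records and promoter windows.

All coordinates are 0-based half-open (BED convention) internally.  GTF input
(1-based closed) is converted at the reader boundary; BED12 is taken as-is.
The promoter window around each TSS is the reference frame for peak-to-gene
assignment.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from intervaltree import IntervalTree

VALID_STRANDS = frozenset("+-")


class AnnotationParseError(ValueError):
    """Raised when a gene-annotation file cannot be parsed."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with a single strand-aware transcription start site.

    ``tss`` is the 5' end of the gene span: ``start`` on the + strand and
    ``end - 1`` on the - strand (last base of the half-open interval).
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PromoterWindow:
    """Symmetric ``[tss - flank, tss + flank)`` window, clipped at 0."""

    gene_id: str
    chrom: str
    start: int
    end: int
    flank: int = 3000


class GenomeAnnotation:
    """Gene collection with per-chromosome overlap and nearest-TSS indexes.

    Overlap queries use an interval tree over gene bodies; nearest-TSS
    queries use a sorted TSS array per chromosome.  Both answer identically
    to a linear scan over the genes (property-tested).
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationParseError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        self._by_id = {g.gene_id: g for g in self.genes}
        self._body_trees: dict[str, IntervalTree] = {}
        self._tss_sorted: dict[str, list[tuple[int, str]]] = {}
        for g in self.genes:
            self._body_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )
            self._tss_sorted.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        for lst in self._tss_sorted.values():
            lst.sort()

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def chroms(self) -> set[str]:
        return set(self._body_trees)

    def overlapping_genes(self, chrom: str, start: int, end: int) -> set[str]:
        """Gene ids whose body overlaps [start, end) by >= 1 bp."""
        tree = self._body_trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def nearest_tss(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """(gene_id, signed distance pos - tss) of the nearest TSS on chrom.

        Ties broken toward the smaller TSS coordinate, then gene_id order in
        the sorted array (deterministic).  Returns None if the chromosome has
        no genes.
        """
        lst = self._tss_sorted.get(chrom)
        if not lst:
            return None
        i = bisect_left(lst, (pos, ""))
        best: tuple[int, int, str] | None = None  # (|dist|, tss, gene_id)
        for j in (i - 1, i):
            if 0 <= j < len(lst):
                tss, gid = lst[j]
                cand = (abs(pos - tss), tss, gid)
                if best is None or cand < best:
                    best = cand
        assert best is not None
        _, tss, gid = best
        return gid, pos - tss


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(attr_field))


def read_gene_annotation(
    path: str | Path, format: Literal["gtf", "bed12"] = "gtf"
) -> GenomeAnnotation:
    """Read gene records from a GTF or BED12 file.

    GTF: only ``gene`` feature lines are used (1-based closed start shifted
    by -1); ``gene_id`` is required, ``gene_name``/``gene_type`` optional.
    BED12: one gene per line, name column as gene_id.

    Raises AnnotationParseError (with line number) on malformed input, an
    unknown strand or a duplicate gene_id; an empty file is an error.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "gtf":
                    if len(fields) < 9:
                        raise ValueError(f"expected 9 GTF columns, got {len(fields)}")
                    if fields[2] != "gene":
                        continue
                    attrs = _parse_gtf_attributes(fields[8])
                    if "gene_id" not in attrs:
                        raise ValueError("missing gene_id attribute")
                    genes.append(
                        GeneModel(
                            gene_id=attrs["gene_id"],
                            symbol=attrs.get("gene_name", attrs["gene_id"]),
                            chrom=fields[0],
                            strand=fields[6],
                            start=int(fields[3]) - 1,
                            end=int(fields[4]),
                            biotype=attrs.get("gene_type", "protein_coding"),
                        )
                    )
                elif format == "bed12":
                    if len(fields) < 6:
                        raise ValueError(f"expected >=6 BED columns, got {len(fields)}")
                    genes.append(
                        GeneModel(
                            gene_id=fields[3],
                            symbol=fields[3],
                            chrom=fields[0],
                            strand=fields[5],
                            start=int(fields[1]),
                            end=int(fields[2]),
                        )
                    )
                else:
                    raise AnnotationParseError(f"unknown format {format!r}")
            except AnnotationParseError:
                raise
            except (ValueError, IndexError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
    if not genes:
        raise AnnotationParseError(f"{path}: no gene records found")
    return GenomeAnnotation(genes)


def write_bed12(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write genes as minimal BED12 (one block spanning the gene)."""
    with open(path, "w") as fh:
        for g in annotation:
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                            g.start, g.end, "0,0,0", 1, g.end - g.start, 0,
                        ],
                    )
                )
                + "\n"
            )


def promoter_windows(
    annotation: GenomeAnnotation, flank: int = 3000
) -> list[PromoterWindow]:
    """One window per gene: ``[tss - flank, tss + flank)`` clipped at 0.

    The window is symmetric regardless of strand; strand only determines
    which gene end is the TSS.  Windows of neighbouring genes may overlap.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    return [
        PromoterWindow(
            gene_id=g.gene_id,
            chrom=g.chrom,
            start=max(0, g.tss - flank),
            end=g.tss + flank,
            flank=flank,
        )
        for g in annotation
    ]


def write_windows_bed6(windows: Iterable[PromoterWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.gene_id}\t0\t+\n")
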