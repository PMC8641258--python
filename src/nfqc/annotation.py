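"""Gene models from GTF annotation: per-gene exon unions, derived introns,
and an interval index for read-overlap queries.

The nuclear-fraction metric needs to know, for every genomic position, whether
it is exonic or intronic for some gene.  Introns are defined per *gene*, not
per transcript: a base is intronic only if it lies inside the gene span but
outside the union of the exons of every isoform.  A read overlapping sequence
that is exonic in any isoform may derive from spliced mRNA, so only purely
intronic evidence marks unspliced pre-mRNA.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "RegionIndex",
    "parse_gtf",
    "build_region_index",
    "write_region_bed",
]

EXONIC = "exonic"
INTRONIC = "intronic"

# GTF2 dialect: key "value"; — GFF3-ish dialect: key=value
_ATTR_GTF2 = re.compile(r'(\w+)\s+"([^"]*)"')
_ATTR_GFF3 = re.compile(r"(\w+)=([^;]+)")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class GeneModel:
    """One gene: merged exon union and the intron gaps between them.

    ``exon_union`` is sorted and merged (no two intervals overlap or abut);
    ``introns`` are exactly the gaps between consecutive exon-union intervals,
    so exons and introns tile the gene span contiguously.
    """

    gene_id: str
    chrom: str
    strand: str
    exon_union: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exon_union[0].start, self.exon_union[-1].end, self.strand
        )

    @classmethod
    def from_exons(
        cls, gene_id: str, chrom: str, strand: str, exons: Iterable[tuple[int, int]]
    ) -> "GeneModel":
        """Build a model from raw (possibly overlapping) exon coordinates."""
        merged = merge_intervals(exons)
        exon_union = [GenomicInterval(chrom, s, e, strand) for s, e in merged]
        introns = [
            GenomicInterval(chrom, a.end, b.start, strand)
            for a, b in zip(exon_union, exon_union[1:])
            if a.end < b.start
        ]
        return cls(gene_id, chrom, strand, exon_union, introns)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge half-open intervals; abutting intervals are joined."""
    ivs = sorted(intervals)
    if not ivs:
        return []
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _parse_attributes(attr: str) -> dict[str, str]:
    attrs = dict(_ATTR_GTF2.findall(attr))
    if "gene_id" not in attrs:
        attrs.update(
            (k, v.strip().strip('"')) for k, v in _ATTR_GFF3.findall(attr)
        )
    return attrs


def _open_text(path) -> Iterator[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        yield from fh


def parse_gtf(path, feature_type: str = "exon") -> list[GeneModel]:
    """Parse a GTF annotation into one :class:`GeneModel` per ``gene_id``.

    Exons from all isoforms of a gene are unioned; GTF 1-based inclusive
    coordinates are converted to 0-based half-open.  Records of other feature
    types, and records lacking a ``gene_id`` attribute, are skipped.

    Parameters
    ----------
    path
        GTF file, plain or gzipped.  Both ``key "value";`` and ``key=value``
        attribute dialects are accepted.
    feature_type
        Feature column value to collect (default ``"exon"``).

    Raises
    ------
    ValueError
        On a malformed line (fewer than 9 tab-separated fields, or an
        unparsable coordinate), naming the offending line number, or when no
        matching feature records are found.
    OSError
        If the file cannot be read.
    """
    exons: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    for lineno, line in enumerate(_open_text(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise ValueError(
                f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, _source, feature, start, end, _score, strand, _frame, attr = fields[:9]
        if feature != feature_type:
            continue
        attrs = _parse_attributes(attr)
        gene_id = attrs.get("gene_id")
        if not gene_id:
            continue
        try:
            s0, e0 = int(start) - 1, int(end)  # GTF is 1-based inclusive
        except ValueError as err:
            raise ValueError(f"{path}: line {lineno}: bad coordinates: {err}") from None
        if strand not in "+-":
            strand = "."
        if gene_id not in exons:
            exons[gene_id] = (chrom, strand, [])
        exons[gene_id][2].append((s0, e0))
    if not exons:
        raise ValueError(f"{path}: no {feature_type} features found")
    return [
        GeneModel.from_exons(gid, chrom, strand, ivs)
        for gid, (chrom, strand, ivs) in exons.items()
    ]


class RegionIndex:
    """Per-chromosome interval lookup over exonic and intronic regions.

    Queries return the set of ``(gene_id, region_class, strand)`` triples
    overlapping a half-open interval; overlapping genes are all reported.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        genes = list(genes)
        if not genes:
            raise ValueError("cannot build a region index from an empty gene list")
        self._trees: dict[str, IntervalTree] = {}
        self.chromosomes: set[str] = set()
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            self.chromosomes.add(g.chrom)
            for iv in g.exon_union:
                tree.addi(iv.start, iv.end, (g.gene_id, EXONIC, g.strand))
            for iv in g.introns:
                tree.addi(iv.start, iv.end, (g.gene_id, INTRONIC, g.strand))

    def query(self, chrom: str, start: int, end: int) -> set[tuple[str, str, str]]:
        """All (gene_id, class, strand) whose region overlaps [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(start, end)}

    def intervals(self) -> Iterator[tuple[str, int, int, str, str, str]]:
        """Yield (chrom, start, end, gene_id, region_class, strand)."""
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                gene_id, cls, strand = iv.data
                yield chrom, iv.begin, iv.end, gene_id, cls, strand


def build_region_index(genes: list[GeneModel]) -> RegionIndex:
    """Index gene models for fast interval-overlap classification."""
    return RegionIndex(genes)


def write_region_bed(index: RegionIndex, path) -> None:
    """Serialize the indexed regions as BED6 (``gene|exonic`` name field)."""
    with open(path, "w") as fh:
        for chrom, start, end, gene_id, cls, strand in index.intervals():
            strand_out = strand if strand in "+-" else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{gene_id}|{cls}\t0\t{strand_out}\n")
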