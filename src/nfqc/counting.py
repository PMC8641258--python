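"""Per-barcode intronic/exonic read counting and the nuclear-fraction score.

The nuclear fraction for droplet *i* is

    NF_i = IR_i / (IR_i + ER_i)

where IR_i and ER_i are the numbers of reads assigned to intronic and exonic
regions.  Reads are classified either from aligner region tags (the ``RE``
tag written by Cell Ranger, values E/N/I) or, when tags are absent, by
overlap against a gene annotation.  Counting is read-based, not UMI-based;
the per-droplet UMI total is a separate axis supplied by the quantification
pipeline.

Traversal is chunked over the genome so large coordinate-sorted BAMs can be
processed in parallel; a read is owned by the chunk containing its leftmost
aligned position, so every read is counted exactly once for any chunking.
"""

from __future__ import annotations

from dataclasses import dataclass
from multiprocessing import get_context
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import EXONIC, INTRONIC, GenomicInterval, RegionIndex

__all__ = [
    "TagConfig",
    "ReadFilter",
    "RegionCounts",
    "partition_genome",
    "count_regions_from_tags",
    "count_regions_from_annotation",
    "compute_nuclear_fraction",
]

STATUS_UNASSIGNED = "unassigned"
STATUS_CELL = "cell"
STATUS_EMPTY = "empty_droplet"
STATUS_DAMAGED = "damaged_cell"


@dataclass(frozen=True)
class TagConfig:
    """SAM auxiliary-tag names and values used for classification.

    Defaults match 10x Genomics Cell Ranger output: cell barcode in ``CB``,
    region type in ``RE`` (``E`` exonic, ``N`` intronic, ``I`` intergenic),
    UMI in ``UB``.
    """

    barcode_tag: str = "CB"
    region_tag: str = "RE"
    exonic_value: str = "E"
    intronic_value: str = "N"
    umi_tag: str = "UB"

    def __post_init__(self) -> None:
        for name in (self.barcode_tag, self.region_tag, self.umi_tag):
            if len(name) != 2:
                raise ValueError(f"SAM auxiliary tag names must be 2 characters, got {name!r}")


@dataclass(frozen=True)
class ReadFilter:
    """Alignment-level filter applied before classification.

    Unmapped, secondary, supplementary and QC-fail reads are excluded by
    default; duplicates are kept because UMI-collapsed pipelines vary in
    whether they mark them.  ``min_mapq`` defaults to 0 (no filter).
    """

    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_qcfail: bool = True
    exclude_duplicates: bool = False
    min_mapq: int = 0

    def passes(self, read: "pysam.AlignedSegment") -> bool:
        if read.is_unmapped:
            return False
        if self.exclude_secondary and read.is_secondary:
            return False
        if self.exclude_supplementary and read.is_supplementary:
            return False
        if self.exclude_qcfail and read.is_qcfail:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        return read.mapping_quality >= self.min_mapq


@dataclass
class RegionCounts:
    """Intronic/exonic read tallies for one cell barcode."""

    barcode: str
    intronic_reads: int = 0
    exonic_reads: int = 0

    def __post_init__(self) -> None:
        if self.intronic_reads < 0 or self.exonic_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.intronic_reads + self.exonic_reads

    @property
    def nuclear_fraction(self) -> float:
        """IR/(IR+ER); NaN when the barcode has no classified reads."""
        if self.total == 0:
            return float("nan")
        return self.intronic_reads / self.total


def partition_genome(references: Mapping[str, int] | Sequence[tuple[str, int]],
                     chunks: int) -> list[GenomicInterval]:
    """Tile every reference sequence into at least ``chunks`` disjoint pieces.

    The genome is cut into roughly equal-sized windows whose total number is
    ``max(chunks, n_references)``; short references contribute one window
    each.  The returned intervals cover every base exactly once.
    """
    if chunks < 1:
        raise ValueError("chunks must be a positive integer")
    items = list(references.items()) if isinstance(references, Mapping) else list(references)
    if not items:
        raise ValueError("empty sequence dictionary: BAM header has no references")
    total = sum(length for _, length in items)
    target = max(1, total // chunks)
    out: list[GenomicInterval] = []
    for name, length in items:
        n_parts = max(1, round(length / target)) if chunks > 1 else 1
        bounds = np.linspace(0, length, n_parts + 1, dtype=int)
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e > s:
                out.append(GenomicInterval(name, int(s), int(e)))
    return out


def _open_bam(path) -> pysam.AlignmentFile:
    bam = pysam.AlignmentFile(str(path), "rb")
    try:
        bam.check_index()
    except (ValueError, AttributeError):
        bam.close()
        raise FileNotFoundError(
            f"{path} has no index (.bai/.csi); create one with `samtools index` "
            "before counting"
        ) from None
    return bam


def _check_region_tag(bam: pysam.AlignmentFile, tags: TagConfig, probe_reads: int) -> None:
    for i, read in enumerate(bam.fetch(until_eof=True)):
        if i >= probe_reads:
            break
        if read.has_tag(tags.region_tag):
            return
    raise ValueError(
        f"region tag {tags.region_tag!r} not found in the first {probe_reads} reads; "
        "the BAM was probably not produced by a region-tagging aligner — use "
        "annotation mode (count_regions_from_annotation / nf-annotation) instead"
    )


def _chunk_counts_tags(args):
    path, chunk, barcodes, tags, read_filter = args
    counts: dict[str, list[int]] = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(chunk.chrom, chunk.start, chunk.end):
            # chunk ownership by leftmost aligned position: exactly-once counting
            if not (chunk.start <= read.reference_start < chunk.end):
                continue
            if not read_filter.passes(read) or not read.has_tag(tags.barcode_tag):
                continue
            bc = read.get_tag(tags.barcode_tag)
            if bc not in barcodes or not read.has_tag(tags.region_tag):
                continue
            region = read.get_tag(tags.region_tag)
            if region == tags.intronic_value:
                counts.setdefault(bc, [0, 0])[0] += 1
            elif region == tags.exonic_value:
                counts.setdefault(bc, [0, 0])[1] += 1
    return counts


def _classify_blocks(blocks, index: RegionIndex, chrom: str, read_strand: str,
                     strand_policy: str, junction_policy: str) -> str | None:
    """Classify a read's aligned blocks as intronic/exonic/None.

    Spliced alignments are evaluated on their aligned blocks only, so the
    skipped (N) intron of a spliced read does not make it intronic.  Under
    the default ``any`` junction policy a single intronic base wins: intronic
    sequence can only come from unspliced RNA, while exonic overlap is
    ambiguous.  ``majority`` classifies by total overlapped bases instead.
    """
    hits: list[tuple[int, int, str]] = []  # (ov_start, ov_end, class)
    for bstart, bend in blocks:
        for gene_id, cls, gstrand in index.query(chrom, bstart, bend):
            if strand_policy == "same" and gstrand in "+-" and gstrand != read_strand:
                continue
            if strand_policy == "opposite" and gstrand in "+-" and gstrand == read_strand:
                continue
            hits.append((bstart, bend, cls))
    if not hits:
        return None
    classes = {cls for _, _, cls in hits}
    if junction_policy == "any":
        return INTRONIC if INTRONIC in classes else EXONIC
    # majority: compare total overlapped bases per class across blocks
    bp = {EXONIC: 0, INTRONIC: 0}
    for bstart, bend in blocks:
        for gene_id, cls, gstrand in index.query(chrom, bstart, bend):
            if strand_policy == "same" and gstrand in "+-" and gstrand != read_strand:
                continue
            if strand_policy == "opposite" and gstrand in "+-" and gstrand == read_strand:
                continue
            bp[cls] += bend - bstart  # upper bound: full block per hit
    if bp[INTRONIC] >= bp[EXONIC]:
        return INTRONIC
    return EXONIC


def _chunk_counts_annotation(args):
    path, chunk, barcodes, tags, read_filter, index, strand_policy, junction_policy = args
    counts: dict[str, list[int]] = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(chunk.chrom, chunk.start, chunk.end):
            if not (chunk.start <= read.reference_start < chunk.end):
                continue
            if not read_filter.passes(read) or not read.has_tag(tags.barcode_tag):
                continue
            bc = read.get_tag(tags.barcode_tag)
            if bc not in barcodes:
                continue
            strand = "-" if read.is_reverse else "+"
            cls = _classify_blocks(
                read.get_blocks(), index, read.reference_name, strand,
                strand_policy, junction_policy,
            )
            if cls == INTRONIC:
                counts.setdefault(bc, [0, 0])[0] += 1
            elif cls == EXONIC:
                counts.setdefault(bc, [0, 0])[1] += 1
    return counts


def _merge_counts(barcodes: Iterable[str], parts) -> list[RegionCounts]:
    totals: dict[str, list[int]] = {bc: [0, 0] for bc in barcodes}
    for part in parts:
        for bc, (ir, er) in part.items():
            totals[bc][0] += ir
            totals[bc][1] += er
    return [RegionCounts(bc, ir, er) for bc, (ir, er) in sorted(totals.items())]


def _run_chunks(worker, jobs, processes: int):
    if processes > 1 and len(jobs) > 1:
        with get_context("spawn").Pool(processes) as pool:
            return pool.map(worker, jobs)
    return [worker(job) for job in jobs]


def count_regions_from_tags(
    bam,
    barcodes: Iterable[str],
    tags: TagConfig | None = None,
    chunks: int = 1,
    read_filter: ReadFilter | None = None,
    probe_reads: int = 1000,
    processes: int = 1,
) -> list[RegionCounts]:
    """Tally intronic/exonic reads per barcode using aligner region tags.

    Every listed barcode is returned, with (0, 0) counts when no qualifying
    read carries it.  Reads whose region tag is neither the intronic nor the
    exonic value (e.g. intergenic), or whose barcode is not listed, are
    ignored; barcodes are matched exactly, including any ``-1`` suffix.
    """
    tags = tags or TagConfig()
    read_filter = read_filter or ReadFilter()
    barcode_set = set(barcodes)
    if not barcode_set:
        raise ValueError("barcode list is empty")
    with _open_bam(bam) as handle:
        refs = list(zip(handle.references, handle.lengths))
        _check_region_tag(handle, tags, probe_reads)
    intervals = partition_genome(refs, chunks)
    jobs = [(bam, chunk, barcode_set, tags, read_filter) for chunk in intervals]
    parts = _run_chunks(_chunk_counts_tags, jobs, processes)
    return _merge_counts(barcode_set, parts)


def count_regions_from_annotation(
    bam,
    index: RegionIndex,
    barcodes: Iterable[str],
    tags: TagConfig | None = None,
    chunks: int = 1,
    read_filter: ReadFilter | None = None,
    strand_policy: str = "ignore",
    junction_policy: str = "any",
    min_chrom_overlap: float = 0.5,
    processes: int = 1,
) -> list[RegionCounts]:
    """Tally intronic/exonic reads per barcode by annotation overlap.

    A read overlapping at least one intronic interval (under
    ``strand_policy``) is intronic; otherwise, overlapping at least one
    exonic interval makes it exonic; otherwise it is ignored.  The BAM and
    the annotation must share chromosome names: fewer than
    ``min_chrom_overlap`` of the BAM references present in the index is
    treated as an annotation/genome mismatch.
    """
    if strand_policy not in ("ignore", "same", "opposite"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    if junction_policy not in ("any", "majority"):
        raise ValueError(f"unknown junction_policy {junction_policy!r}")
    tags = tags or TagConfig()
    read_filter = read_filter or ReadFilter()
    barcode_set = set(barcodes)
    if not barcode_set:
        raise ValueError("barcode list is empty")
    with _open_bam(bam) as handle:
        refs = list(zip(handle.references, handle.lengths))
    shared = {name for name, _ in refs} & index.chromosomes
    if not shared:
        raise ValueError(
            "annotation/genome mismatch: no chromosome names shared between "
            "the BAM and the annotation"
        )
    if len(shared) / len(refs) < min_chrom_overlap:
        raise ValueError(
            f"annotation/genome mismatch: only {len(shared)}/{len(refs)} BAM "
            "references appear in the annotation"
        )
    intervals = partition_genome(refs, chunks)
    jobs = [
        (bam, chunk, barcode_set, tags, read_filter, index, strand_policy, junction_policy)
        for chunk in intervals
    ]
    parts = _run_chunks(_chunk_counts_annotation, jobs, processes)
    return _merge_counts(barcode_set, parts)


def compute_nuclear_fraction(
    counts: list[RegionCounts],
    umi: Mapping[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """Build the per-droplet table with NF scores from region counts.

    Returns a DataFrame with columns ``barcode``, ``intronic_reads``,
    ``exonic_reads``, ``nuclear_fraction``, ``umi_count``, ``cell_type``,
    ``qc_status``.  Barcodes with no classified reads get NaN nuclear
    fraction and are excluded from downstream calling (status stays
    ``unassigned``).
    """
    barcodes = [c.barcode for c in counts]
    if len(set(barcodes)) != len(barcodes):
        dupes = pd.Series(barcodes).value_counts()
        raise ValueError(
            f"duplicate barcodes in counts: {list(dupes[dupes > 1].index[:5])}"
        )
    table = pd.DataFrame(
        {
            "barcode": barcodes,
            "intronic_reads": [c.intronic_reads for c in counts],
            "exonic_reads": [c.exonic_reads for c in counts],
            "nuclear_fraction": [c.nuclear_fraction for c in counts],
        }
    )
    if umi is None:
        table["umi_count"] = 0
    else:
        umi = pd.Series(umi)
        table["umi_count"] = table["barcode"].map(umi).fillna(0).astype(int)
    table["cell_type"] = pd.NA
    table["qc_status"] = STATUS_UNASSIGNED
    return table
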