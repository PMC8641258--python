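"""Ground-truthed synthetic fixtures: annotation, tagged BAMs, droplet tables.

Every generator records exact per-barcode truth (a *ledger*) so the counting
and calling code can be validated without external data.  The droplet
populations emulate the qualitative geometry of droplet scRNA-seq QC:

* **empty droplets** — ambient RNA only: NF concentrated near ~0.05 (Beta),
  low UMI totals;
* **intact cells** — a mix of spliced and unspliced RNA: NF around ~0.4
  (truncated normal), the largest UMI totals;
* **damaged cells** — cytoplasm-depleted: NF around ~0.75, UMI totals at
  ~30% of the intact mean of the same cell type.

UMI totals are log10-normal.  Reads in the synthetic BAM are placed entirely
within a single exonic or intronic interval (no junction-spanning reads by
default), so region-tag counting and annotation-overlap counting agree
exactly; a junction-read fraction can be enabled to exercise the junction
policy.  Sequence content is dummy — classification depends only on
coordinates and tags.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .annotation import GeneModel
from .counting import STATUS_UNASSIGNED

__all__ = [
    "ClassSpec",
    "CellTypeSpec",
    "PopulationSpec",
    "make_annotation",
    "make_bam",
    "make_droplet_table",
    "write_bundle",
]

CLASS_EMPTY = "empty"
CLASS_INTACT = "intact"
CLASS_DAMAGED = "damaged"


@dataclass
class ClassSpec:
    """Sampling law for one droplet class.

    ``nf`` is either ``{"dist": "beta", "a": ..., "b": ...}`` or
    ``{"dist": "truncnorm", "mean": ..., "sd": ...}`` (truncated to [0, 1]);
    ``log10_umi`` is a normal on the log10 scale.
    """

    n: int
    nf: dict = field(default_factory=dict)
    log10_umi: dict = field(default_factory=dict)

    def nf_mean(self) -> float:
        if self.nf["dist"] == "beta":
            return self.nf["a"] / (self.nf["a"] + self.nf["b"])
        return self.nf["mean"]

    def sample_nf(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.nf["dist"] == "beta":
            return rng.beta(self.nf["a"], self.nf["b"], size=n)
        if self.nf["dist"] == "truncnorm":
            mean, sd = self.nf["mean"], self.nf["sd"]
            a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
            return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        raise ValueError(f"unknown NF distribution {self.nf!r}")

    def sample_umi(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.normal(self.log10_umi["mean"], self.log10_umi["sd"], size=n)
        return np.maximum(1, np.round(10.0 ** x)).astype(int)


@dataclass
class CellTypeSpec:
    intact: ClassSpec
    damaged: ClassSpec


@dataclass
class PopulationSpec:
    """Composition of a synthetic droplet population, with a seed."""

    empty: ClassSpec
    cell_types: dict[str, CellTypeSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        for name, ct in self.cell_types.items():
            if not self.empty.nf_mean() < ct.intact.nf_mean() < ct.damaged.nf_mean():
                raise ValueError(
                    f"{name}: class NF means must be ordered empty < intact < damaged"
                )
            if not ct.damaged.log10_umi["mean"] < ct.intact.log10_umi["mean"]:
                raise ValueError(f"{name}: damaged UMI mean must be below intact")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "empty": vars(self.empty),
            "cell_types": {
                name: {"intact": vars(ct.intact), "damaged": vars(ct.damaged)}
                for name, ct in self.cell_types.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        return cls(
            empty=ClassSpec(**d["empty"]),
            cell_types={
                name: CellTypeSpec(
                    intact=ClassSpec(**ct["intact"]),
                    damaged=ClassSpec(**ct["damaged"]),
                )
                for name, ct in d["cell_types"].items()
            },
            seed=d.get("seed", 0),
        )


def _class_spec(n, nf, umi) -> ClassSpec:
    return ClassSpec(n=n, nf=nf, log10_umi=umi)


def default_population_spec(seed: int = 0) -> PopulationSpec:
    """A 5,000-droplet population: 10% empty, three cell types, 20% of each
    type's droplets damaged."""
    types = {}
    for name, nf_mean, umi_mean in [
        ("type_A", 0.35, 3.3), ("type_B", 0.40, 3.5), ("type_C", 0.45, 3.7),
    ]:
        types[name] = CellTypeSpec(
            intact=_class_spec(
                1200, {"dist": "truncnorm", "mean": nf_mean, "sd": 0.06},
                {"mean": umi_mean, "sd": 0.2},
            ),
            damaged=_class_spec(
                300, {"dist": "truncnorm", "mean": nf_mean + 0.35, "sd": 0.05},
                {"mean": umi_mean + np.log10(0.3), "sd": 0.2},
            ),
        )
    return PopulationSpec(
        empty=_class_spec(500, {"dist": "beta", "a": 2, "b": 38},
                          {"mean": 2.3, "sd": 0.25}),
        cell_types=types,
        seed=seed,
    )


def small_population_spec(seed: int = 0) -> PopulationSpec:
    """A 500-barcode population sized for BAM-level counting fixtures."""
    return PopulationSpec(
        empty=_class_spec(50, {"dist": "beta", "a": 2, "b": 38},
                          {"mean": 2.3, "sd": 0.25}),
        cell_types={
            "type_A": CellTypeSpec(
                intact=_class_spec(360, {"dist": "truncnorm", "mean": 0.4, "sd": 0.06},
                                   {"mean": 3.5, "sd": 0.2}),
                damaged=_class_spec(90, {"dist": "truncnorm", "mean": 0.75, "sd": 0.05},
                                    {"mean": 3.5 + np.log10(0.3), "sd": 0.2}),
            )
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# annotation


def make_annotation(n_genes: int, seed: int, contigs=(("chrS1", 300_000),
                                                      ("chrS2", 300_000),
                                                      ("chrS3", 300_000)),
                    min_exon: int = 150, max_exon: int = 400,
                    min_intron: int = 200, max_intron: int = 800,
                    gtf_path=None) -> tuple[list[str], list[GeneModel]]:
    """Random multi-isoform genes on a small synthetic genome.

    Genes are laid out left to right with intergenic gaps, so gene spans
    never overlap.  Each gene gets 1-3 transcripts; the first transcript
    carries the full exon set, so the per-gene exon union is exactly the
    designed one.  Returns the GTF lines and the in-memory gene models; when
    ``gtf_path`` is given the lines are also written there.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    models: list[GeneModel] = []
    cursors = {name: 500 for name, _ in contigs}
    lengths = dict(contigs)
    for i in range(n_genes):
        chrom = contigs[i % len(contigs)][0]
        n_exons = int(rng.integers(2, 7))
        exons = []
        pos = cursors[chrom]
        for j in range(n_exons):
            e_len = int(rng.integers(min_exon, max_exon + 1))
            exons.append((pos, pos + e_len))
            pos += e_len
            if j < n_exons - 1:
                pos += int(rng.integers(min_intron, max_intron + 1))
        if pos + 500 > lengths[chrom]:
            raise ValueError(
                f"synthetic contig {chrom} too short for {n_genes} genes; "
                "use fewer genes or longer contigs"
            )
        cursors[chrom] = pos + int(rng.integers(500, 1500))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"SYNG{i:04d}"
        models.append(GeneModel.from_exons(gene_id, chrom, strand, exons))
        n_tx = int(rng.integers(1, 4))
        for t in range(n_tx):
            if t == 0:
                tx_exons = exons  # full set: union equals the design
            else:
                keep = rng.random(n_exons) < 0.7
                keep[int(rng.integers(0, n_exons))] = True
                tx_exons = [e for e, k in zip(exons, keep) if k]
            tx_id = f"{gene_id}.t{t+1}"
            for s, e in tx_exons:
                attr = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
                # GTF is 1-based inclusive
                lines.append(
                    f"{chrom}\tnfqc_sim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attr}"
                )
    if gtf_path is not None:
        Path(gtf_path).write_text("\n".join(lines) + "\n")
    return lines, models


# ---------------------------------------------------------------------------
# droplet tables


def make_droplet_table(spec: PopulationSpec, seed: int | None = None):
    """Sample (NF, UMI, cell type) per droplet; truth labels returned
    separately.  Read tallies consistent with the sampled NF are included so
    the table can stand in for counting output."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    groups: list[tuple[str, str | None, ClassSpec]] = [
        (CLASS_EMPTY, None, spec.empty)
    ]
    for name, ct in spec.cell_types.items():
        groups.append((CLASS_INTACT, name, ct.intact))
        groups.append((CLASS_DAMAGED, name, ct.damaged))
    idx = 0
    for cls, cell_type, cspec in groups:
        nf = cspec.sample_nf(rng, cspec.n)
        umi = cspec.sample_umi(rng, cspec.n)
        for j in range(cspec.n):
            rows.append((f"BC{idx:06d}-1", cls, cell_type, float(nf[j]), int(umi[j])))
            idx += 1
    df = pd.DataFrame(rows, columns=["barcode", "true_class", "cell_type",
                                     "nuclear_fraction", "umi_count"])
    total = 200
    df["intronic_reads"] = np.round(total * df["nuclear_fraction"]).astype(int)
    df["exonic_reads"] = total - df["intronic_reads"]
    df["qc_status"] = STATUS_UNASSIGNED
    labels = df[["barcode", "true_class", "cell_type"]].copy()
    table = df[["barcode", "intronic_reads", "exonic_reads", "nuclear_fraction",
                "umi_count", "cell_type", "qc_status"]].copy()
    return table, labels


# ---------------------------------------------------------------------------
# BAM emission


def make_bam(spec: PopulationSpec, genes: list[GeneModel], bam_path,
             write_region_tags: bool = True, seed: int | None = None,
             reads_per_barcode: int = 100, read_length: int = 90,
             intergenic_fraction: float = 0.05,
             junction_fraction: float = 0.0,
             contigs=(("chrS1", 300_000), ("chrS2", 300_000), ("chrS3", 300_000)),
             ) -> pd.DataFrame:
    """Emit a coordinate-sorted, indexed BAM realizing each barcode's target
    NF, plus the exact per-barcode ledger.

    Each barcode draws a target NF from its class law; its reads are split
    into intergenic / intronic / exonic by binomial draws and each read is
    placed entirely inside an interval of the corresponding class (intergenic
    reads go into gaps between genes).  When ``junction_fraction > 0`` that
    share of a barcode's classified reads instead straddles an exon/intron
    boundary; under the any-intronic-overlap policy these count as intronic,
    and the ledger records them as such.  Tags written: ``CB`` always,
    ``RE``/``UB`` when ``write_region_tags``.

    Returns the ledger with columns ``barcode, true_class, cell_type,
    intronic_reads, exonic_reads, intergenic_reads, umi_count, nf_target``.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    exon_ivs, intron_ivs, junctions = [], [], []
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        spans.setdefault(g.chrom, []).append((g.span.start, g.span.end))
        for iv in g.exon_union:
            if len(iv) >= read_length:
                exon_ivs.append((g.chrom, iv.start, iv.end))
        for iv in g.introns:
            if len(iv) >= read_length:
                intron_ivs.append((g.chrom, iv.start, iv.end))
        for a, b in zip(g.exon_union, g.exon_union[1:]):
            # exon->intron boundary at a.end; need room on both sides
            if a.end - a.start >= read_length and b.start - a.end >= read_length:
                junctions.append((g.chrom, a.end))
    if not exon_ivs or not intron_ivs:
        raise ValueError(
            f"no exon or intron interval can hold a {read_length} bp read; "
            "regenerate the annotation with longer intervals"
        )
    gaps = []
    lengths = dict(contigs)
    for chrom, length in contigs:
        prev = 0
        for s, e in sorted(spans.get(chrom, [])):
            if s - prev >= read_length + 2:
                gaps.append((chrom, prev + 1, s - 1))
            prev = max(prev, e)
        if length - prev >= read_length + 2:
            gaps.append((chrom, prev + 1, length - 1))

    def _place(rng, ivs):
        chrom, s, e = ivs[rng.integers(0, len(ivs))]
        return chrom, int(rng.integers(s, e - read_length + 1))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs],
    }
    ref_id = {name: i for i, (name, _) in enumerate(contigs)}

    groups: list[tuple[str, str | None, ClassSpec]] = [(CLASS_EMPTY, None, spec.empty)]
    for name, ct in spec.cell_types.items():
        groups.append((CLASS_INTACT, name, ct.intact))
        groups.append((CLASS_DAMAGED, name, ct.damaged))

    reads = []  # (ref_id, pos, barcode, region_value, umi)
    ledger_rows = []
    idx = 0
    for cls, cell_type, cspec in groups:
        nf_targets = cspec.sample_nf(rng, cspec.n)
        umis = cspec.sample_umi(rng, cspec.n)
        for j in range(cspec.n):
            barcode = f"BC{idx:06d}-1"
            idx += 1
            n_intergenic = int(rng.binomial(reads_per_barcode, intergenic_fraction))
            n_classified = reads_per_barcode - n_intergenic
            n_junction = int(rng.binomial(n_classified, junction_fraction))
            n_plain = n_classified - n_junction
            n_intronic = int(rng.binomial(n_plain, nf_targets[j]))
            n_exonic = n_plain - n_intronic
            for _ in range(n_intronic):
                chrom, pos = _place(rng, intron_ivs)
                reads.append((ref_id[chrom], pos, barcode, "N"))
            for _ in range(n_exonic):
                chrom, pos = _place(rng, exon_ivs)
                reads.append((ref_id[chrom], pos, barcode, "E"))
            for _ in range(n_junction):
                chrom, bnd = junctions[rng.integers(0, len(junctions))]
                offset = int(rng.integers(1, read_length))  # 1..L-1 bases past boundary
                reads.append((ref_id[chrom], bnd - (read_length - offset), barcode, "N"))
            for _ in range(n_intergenic):
                if gaps:
                    chrom, s, e = gaps[rng.integers(0, len(gaps))]
                    pos = int(rng.integers(s, e - read_length + 1))
                    reads.append((ref_id[chrom], pos, barcode, "I"))
            ledger_rows.append((
                barcode, cls, cell_type,
                n_intronic + n_junction, n_exonic,
                n_intergenic if gaps else 0,
                int(umis[j]), float(nf_targets[j]),
            ))

    reads.sort(key=lambda r: (r[0], r[1], r[2]))
    bam_path = str(bam_path)
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for i, (rid, pos, barcode, region) in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i:07d}"
            a.reference_id = rid
            a.reference_start = pos
            a.mapping_quality = 255
            a.cigarstring = f"{read_length}M"
            a.query_sequence = "A" * read_length
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            a.flag = 0
            tags = [("CB", barcode)]
            if write_region_tags:
                tags += [("RE", region), ("UB", f"UMI{i % 4096:04d}")]
            a.set_tags(tags)
            out.write(a)
    pysam.index(bam_path)

    return pd.DataFrame(ledger_rows, columns=[
        "barcode", "true_class", "cell_type", "intronic_reads", "exonic_reads",
        "intergenic_reads", "umi_count", "nf_target",
    ])


# ---------------------------------------------------------------------------
# bundles


def write_bundle(outdir, spec: PopulationSpec | None = None, seed: int = 0,
                 n_genes: int = 60, write_region_tags: bool = True,
                 reads_per_barcode: int = 100) -> dict[str, Path]:
    """Emit a complete fixture bundle: GTF, BAM (+index), barcodes.tsv.gz,
    UMI TSV, truth labels TSV and the population spec as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or small_population_spec(seed=seed)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "bam": outdir / "reads.bam",
        "barcodes": outdir / "barcodes.tsv.gz",
        "umi": outdir / "umi_counts.tsv",
        "labels": outdir / "labels.tsv",
        "spec": outdir / "population_spec.json",
    }
    _, genes = make_annotation(n_genes, seed=seed, gtf_path=paths["gtf"])
    ledger = make_bam(spec, genes, paths["bam"], write_region_tags=write_region_tags,
                      seed=seed, reads_per_barcode=reads_per_barcode)
    with open(paths["barcodes"], "wb") as raw:
        # mtime=0 keeps rewrites of the same content byte-identical
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
            fh.write(("\n".join(ledger["barcode"]) + "\n").encode())
    ledger[["barcode", "umi_count"]].to_csv(paths["umi"], sep="\t",
                                            header=False, index=False)
    ledger.to_csv(paths["labels"], sep="\t", index=False)
    paths["spec"].write_text(json.dumps(spec.to_dict(), indent=2) + "\n")
    return paths
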