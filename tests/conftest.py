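"""Shared fixtures: synthetic annotation, BAM bundles and droplet tables.

All fixtures are generated at test time with fixed seeds; nothing is read
from outside the repository.
"""

import numpy as np
import pandas as pd
import pysam
import pytest

import nfqc


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Full tagged fixture bundle: 500 barcodes x 100 reads = 50,000 reads."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = nfqc.write_bundle(outdir, seed=11, n_genes=60, reads_per_barcode=100)
    ledger = pd.read_csv(paths["labels"], sep="\t")
    return paths, ledger


@pytest.fixture(scope="session")
def genes(bundle):
    paths, _ = bundle
    return nfqc.parse_gtf(paths["gtf"])


@pytest.fixture(scope="session")
def region_index(genes):
    return nfqc.build_region_index(genes)


@pytest.fixture(scope="session")
def tag_counts(bundle):
    paths, _ = bundle
    barcodes = nfqc.read_barcodes(paths["barcodes"])
    return nfqc.count_regions_from_tags(paths["bam"], barcodes)


def counts_frame(counts):
    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in counts],
            "intronic_reads": [c.intronic_reads for c in counts],
            "exonic_reads": [c.exonic_reads for c in counts],
        }
    ).set_index("barcode").sort_index()


def ledger_frame(ledger):
    return (
        ledger[["barcode", "intronic_reads", "exonic_reads"]]
        .set_index("barcode")
        .sort_index()
    )


@pytest.fixture()
def mini_bam(tmp_path):
    """Hand-built 3-barcode tagged BAM on one 10 kb contig.

    AAAC: 7 intronic + 3 exonic + 2 intergenic reads; GGGT: 1 exonic;
    TTTG appears in barcode lists but not in the BAM.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chrM1", "LN": 10000}]}
    reads = []
    for i in range(7):
        reads.append((100 + i, "AAAC", "N"))
    for i in range(3):
        reads.append((300 + i, "AAAC", "E"))
    for i in range(2):
        reads.append((500 + i, "AAAC", "I"))
    reads.append((700, "GGGT", "E"))
    path = tmp_path / "mini.bam"
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for i, (pos, bc, region) in enumerate(sorted(reads)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = "50M"
            a.query_sequence = "A" * 50
            a.flag = 0
            a.set_tags([("CB", bc), ("RE", region)])
            out.write(a)
    pysam.index(str(path))
    return path


@pytest.fixture(scope="session")
def population():
    """Default 5,000-droplet population with truth labels."""
    spec = nfqc.default_population_spec(seed=7)
    table, labels = nfqc.make_droplet_table(spec)
    return spec, table, labels


def simulate_mixture(n, means, variances, weights, seed):
    """Draw (log10 UMI, NF) pairs from a known diagonal-Gaussian mixture."""
    rng = np.random.default_rng(seed)
    comps = rng.choice(len(weights), size=n, p=weights)
    means = np.asarray(means, dtype=float)
    sds = np.sqrt(np.asarray(variances, dtype=float))
    X = rng.normal(means[comps], sds[comps])
    return X, comps
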