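# nfqc — nuclear-fraction QC for droplet scRNA-seq

Droplet scRNA-seq libraries contain, besides intact cells, droplets holding
only cell-free **ambient RNA** (empty droplets) and droplets holding
**damaged cells** — partially lysed cells depleted of cytoplasmic RNA.
Standard cell-calling and UMI cutoffs retain many of both. `nfqc` flags them
using the **nuclear fraction**: per droplet *i*, the share of aligned reads
that come from intronic (unspliced, nuclear pre-mRNA) sequence,

```
NF_i = IR_i / (IR_i + ER_i)
```

where IR_i and ER_i are droplet *i*'s intronic and exonic read counts.
Ambient RNA is predominantly mature, spliced mRNA, so empty droplets sit at
distinctly low NF; damaged cells, having lost cytoplasm but kept their
nucleus, sit at high NF with reduced UMI totals. On these two axes —
log₁₀(UMI) and NF — the three populations separate:

* **Empty droplets** are everything below a cutoff found automatically as
  the first valley (via the first derivative) of a kernel density estimate
  of the NF scores, with manual NF/UMI rescue thresholds as overrides.
* **Damaged cells** are found per cell type by fitting a two-component
  Gaussian mixture P(x|μ,σ,α) = α₁N(x|μ₁,σ₁²) + α₂N(x|μ₂,σ₂²) on
  (log₁₀ UMI, NF) with expectation-maximization; BIC decides whether a
  second component exists, and it is flagged only if it has both higher mean
  NF (by ≥ 0.15 by default) and lower mean UMI (≤ 50% of the intact mean).

Barcodes are flagged, never removed. The intended users are people running
single-cell pipelines on 10x Genomics-style BAMs (Cell Ranger, STARsolo)
who want an orthogonal QC axis after cell calling with tools like
EmptyDrops. See `docs/methods.md` for the full model description.

## Worked example

Everything below runs on synthetic data generated by the package itself —
no downloads. `write_bundle` emits an indexed BAM with `CB`/`RE`/`UB` tags,
a GTF, a barcode list, UMI totals, and a ground-truth ledger for 500
barcodes (50 empty, 360 intact, 90 damaged).

```python
import tempfile, nfqc, pandas as pd
from pathlib import Path

workdir = Path(tempfile.mkdtemp())
paths = nfqc.write_bundle(workdir / "sim", seed=7)

barcodes = nfqc.read_barcodes(paths["barcodes"])
counts = nfqc.count_regions_from_tags(paths["bam"], barcodes)
table = nfqc.compute_nuclear_fraction(counts, nfqc.read_umi_counts(paths["umi"]))

labels = pd.read_csv(paths["labels"], sep="\t")
table["cell_type"] = table["barcode"].map(labels.set_index("barcode")["cell_type"])

flagged, report = nfqc.call_all(table, nfqc.CallConfig(seed=7))
print("empty-droplet NF cutoff:", round(report["empty_threshold"]["cutoff"], 4))
print(flagged["qc_status"].value_counts().to_dict())
```

which prints

```
empty-droplet NF cutoff: 0.1526
{'cell': 359, 'damaged_cell': 93, 'empty_droplet': 48}
```

The KDE valley lands at NF ≈ 0.15, between the empty mode (NF ≈ 0.05) and
the intact mode (NF ≈ 0.4): 48 of the 50 planted empty droplets fall below
it. BIC selects two components for the one cell type, and the
higher-NF/lower-UMI component passes both separation gates: all 90 planted
damaged cells are flagged (93 calls total). Without region tags, replace the
counting step with annotation mode:

```python
genes = nfqc.parse_gtf(paths["gtf"])
index = nfqc.build_region_index(genes)
counts = nfqc.count_regions_from_annotation(paths["bam"], index, barcodes)
```

Both modes reproduce the generator's ledger exactly on this fixture.

The same pipeline from the shell:

```bash
nfqc simulate --out-dir sim --seed 7
nfqc nf-tags --bam sim/reads.bam --barcodes sim/barcodes.tsv.gz \
     --umi sim/umi_counts.tsv --out nf.tsv --chunks 4
nfqc call --table nf.tsv --out called.tsv --report report.json --seed 7
```

`nfqc nf-annotation --gtf sim/annotation.gtf ...` is the tag-free variant;
`--chunks`/`--processes` control genome-chunked parallel counting (results
are bit-identical for any chunking).

The statistical core is also usable directly as scikit-learn-style
estimators (`EmptyDropletDetector`, `DiagonalGaussianMixture`,
`DamagedCellDetector` in `nfqc.calling`) with `fit`/`predict` and
`get_params`/`set_params`.

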