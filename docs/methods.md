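# Methods

## The nuclear fraction

Droplet scRNA-seq captures, alongside cells, cell-free "ambient" RNA released
by lysed and damaged cells. Ambient RNA is predominantly mature, spliced
cytoplasmic mRNA, whereas an intact cell contributes a mixture of mature
mRNA and unspliced nuclear pre-mRNA. The per-droplet **nuclear fraction**

```
NF_i = IR_i / (IR_i + ER_i)
```

— the share of droplet *i*'s aligned reads that map to intronic rather than
exonic sequence — therefore separates three droplet populations:

* **empty droplets** (ambient RNA only): low NF, typically low UMI totals;
* **intact cells**: intermediate NF;
* **damaged cells** (partially lysed, cytoplasm depleted but nucleus
  retained): high NF and reduced UMI totals relative to intact cells of the
  same type.

NF counts **reads**, not UMIs; the per-droplet UMI total is a separate axis
supplied by the quantification pipeline (two-column TSV or column sums of an
MTX matrix), or optionally recomputed upstream. Reads are classified by one
of two routes:

1. **Tag mode** (`count_regions_from_tags`) trusts aligner region tags —
   Cell Ranger writes `RE` with values `E`/`N`/`I` (exonic / intronic /
   intergenic) and the cell barcode in `CB`. Reads whose region tag is
   neither the exonic nor the intronic value are ignored.
2. **Annotation mode** (`count_regions_from_annotation`) classifies each
   read by overlap against intervals derived from a GTF: per gene, the exon
   union across all isoforms, and introns as the gaps between consecutive
   union intervals. Intronic status is per *gene*, not per transcript — a
   base exonic in any isoform may derive from spliced mRNA, so only purely
   intronic overlap is treated as evidence of unspliced RNA.

### Classification policies (annotation mode)

These are deliberate choices where the procedure is underdetermined; all are
exposed as configuration:

* **Junction policy** (default `any`): a read with *any* intronic overlap is
  intronic, even if it also overlaps exon — intronic sequence can only come
  from unspliced RNA, while exonic overlap is ambiguous. A `majority`
  (most-overlapped-bases) alternative is provided.
* **Strand policy** (default `ignore`): library strandedness varies across
  3′ and 5′ chemistries; `same`/`opposite` modes serve stranded data. A read
  intronic in one gene and exonic in an overlapping gene is intronic under
  the default (consistent with the junction policy).
* **Read filter**: unmapped, secondary, supplementary and QC-fail alignments
  are excluded; duplicates are kept (UMI-collapsed pipelines differ in
  whether duplicates are marked); MAPQ threshold default 0.
* **Spliced alignments** are evaluated on their aligned blocks only — the
  `N` gap of a spliced read does not make it intronic.
* **Barcodes** are matched exactly (including `-1` style suffixes); barcode
  correction belongs upstream.

### Chunked traversal

The genome is tiled into a user-chosen number of windows
(`partition_genome`); each window is counted independently (optionally in
parallel processes) and results are summed. A read is *owned* by the window
containing its leftmost aligned position, so reads spanning a window
boundary are counted exactly once and results are bit-identical for every
chunking. Barcodes with no classified reads get NF = NA and are excluded
from all downstream calling.

## Empty-droplet threshold

A Gaussian KDE of the defined NF scores is evaluated on a 512-point grid
over [0, 1] with Silverman's rule bandwidth. Mass is reflected at both
boundaries (density(x) += density(−x) + density(2−x)) so the estimate
integrates to ≈1 over the unit interval even when the empty-droplet mode
sits near 0. Peaks and valleys are sign changes of the numerical first
difference (plateaus inherit the preceding slope; boundary extrema are
detected by padding); a peak must reach 5% of the global density maximum to
count, which suppresses noise wiggles. The cutoff is the first valley
between the first two qualifying peaks; droplets with NF below it are
flagged `empty_droplet`. If the smoothed density is unimodal no cutoff is
reported and the caller must supply one. Two manual overrides exist: a fixed
NF threshold (`nf_rescue`) replacing the automatic cutoff, and a UMI total
(`umi_rescue`) above which a barcode is always kept as a cell. Automatic
thresholding refuses to run on fewer than 50 defined NF values.

**Known limitation.** The valley of a kernel density estimate tracks the
analytic minimum of the underlying mixture density only while the components
overlap appreciably. For extremely separated, sharp components the true
density minimum lies deep in a region containing no observations (density
~1e-11 for, e.g., 0.3·N(0.05, 0.01²) + 0.7·N(0.5, 0.05²), whose minimum is
at ≈0.128), and the estimated valley of *any* bandwidth settles near the
midpoint of the empirical gap (~0.21–0.23 at n = 5,000). The cutoff still
separates the two populations perfectly in such cases; it is the exact
valley *location* within an empty gap that is not estimable from data.

## Damaged-cell mixture model

Because UMI totals and NF distributions differ between cell types, damaged
cells are sought separately within each user-supplied cell-type label, among
droplets already called `cell`. On x = (log10 UMI, NF) a two-component
Gaussian mixture with diagonal covariance

```
P(x | μ, σ, α) = α₁ N(x | μ₁, σ₁²) + α₂ N(x | μ₂, σ₂²)
```

is fitted by EM:

* **Initialization** is deterministic and seed-free: droplets are split at
  the median NF of the group; each half supplies its component's initial
  mean, biased variance (denominator N_k) and weight α_k = N_k / N.
* **E-step**: posterior responsibilities by Bayes' rule,
  P(x_i ∈ k_j | x_i) = α_j N(x_i | μ_j, σ_j²) / Σ_k α_k N(x_i | μ_k, σ_k²),
  computed in log space.
* **M-step**: responsibility-weighted refits of μ, σ² and α.
* **Stopping**: relative log-likelihood change < 1e-6 (default), max 1,000
  iterations. The reported log-likelihood is evaluated at the returned
  parameters, so it matches an independent density evaluation exactly, and
  the iteration trace is monotone non-decreasing.
* **Degeneracy guard**: a per-dimension variance floor of 1e-6; component
  collapse triggers up to three re-initializations at random quantile splits
  (the only seeded step) before failing.

Model order is chosen by BIC = −2·loglik + p·ln(n) with p = 2kd + (k−1)
free parameters (d = 2): the two-component model is accepted only when its
BIC is lower than the single-component fit's. This is deliberately read as
*model selection*, not as an iteration stopping rule: BIC decides whether a
distinct second population exists at all, i.e. the minimum separation
required before any droplet may be called damaged.

When k = 2 wins, the **candidate** component must exhibit the damaged-cell
phenotype on *both* axes: the higher mean NF and the lower mean UMI. Two
separation gates then apply (defaults 0.15 and 50%):

* ΔNF = μ_NF(candidate) − μ_NF(other) ≥ `delta_nf`;
* mean UMI(candidate) ≤ `umi_ratio` × mean UMI(other), compared on the
  linear scale via geometric means (10^mean-of-log10 — the model-consistent
  center since the mixture lives in log space).

Only if both gates pass are droplets with candidate posterior > 0.5
(maximum a posteriori) flagged `damaged_cell`. Groups smaller than
`min_droplets_per_type` (default 100) are skipped with a warning — mixture
fits on tiny groups are unstable. The pipeline (`call_all`) resets statuses,
flags empty droplets, then processes each cell type; statuses are flags
only, rows are never removed (a `--drop-flagged` CLI switch removes them
explicitly).

## Parameters at a glance

| parameter | default | meaning |
|---|---|---|
| `nf_rescue` | unset | manual NF cutoff (fraction in [0,1]) replacing the KDE valley |
| `umi_rescue` | unset | UMI total above which a barcode is always a cell |
| `delta_nf` | 0.15 | minimum NF-mean separation (fraction) for damaged calls |
| `umi_ratio` | 0.5 | max damaged/intact mean-UMI ratio (linear scale) |
| `min_droplets_per_type` | 100 | smallest group the mixture is fitted on |
| `em_tol`, `em_max_iter` | 1e-6, 1000 | EM stopping rule |
| `bandwidth`, `grid_size`, `prominence` | silverman, 512, 0.05 | KDE settings |
| `min_nf_values` | 50 | floor for automatic thresholding |
| `variance_floor` | 1e-6 | EM collapse guard, per dimension |
| chunks / processes | 1 / 1 | genome windows and worker processes |

## Synthetic data

The fixture generator emulates the study conditions with exact ground
truth. The default population holds 5,000 droplets: 500 empty (10%) and
three cell types of 1,200 intact + 300 damaged droplets each (20% damaged
per type). NF laws: empty ~ Beta(2, 38) (mean 0.05); intact ~ truncated
normal with means 0.35/0.40/0.45 and sd 0.06; damaged ~ intact mean + 0.35,
sd 0.05. UMI totals are log10-normal with intact means 10^3.3/10^3.5/10^3.7
(sd 0.2 dex) and damaged geometric means at 30% of intact. Parameter-recovery
checks scale each type to 1,600 + 400 = 2,000 droplets. A 500-barcode
variant (one cell type) at 100 reads per barcode yields the 50,000-read
BAM used for counting checks.

Synthetic BAMs place each read entirely inside one exonic or intronic
interval of a randomly generated multi-isoform annotation (3 × 300 kb
contigs; exons 150–400 bp, introns 200–800 bp; the first transcript of each
gene carries the full exon set so the per-gene union is exact), so tag mode
and annotation mode agree read-for-read; an optional junction-read fraction
plants boundary-spanning reads (ledgered as intronic, per the `any` policy)
to exercise the junction rule. Intergenic reads (default 5%) are placed in
gaps between genes and must be ignored by both modes.

What the generator does **not** emulate: real sequence content, sequencing
error, barcode errors, ambient-RNA *expression profiles* (droplets are
independent; there is no shared ambient pool), doublets, cell-type
annotation error, or per-gene expression structure. Passing tests therefore
demonstrate correctness of counting, thresholding and mixture inference
under the stated population geometry — not robustness to annotation quality,
protocol strandedness, or misannotated cell types, which the configuration
switches exist to address on real data.

## Numerical notes

* All randomness flows through `numpy.random.default_rng` seeds; EM is
  seed-free unless a collapse retry occurs, so identical inputs give
  bit-identical outputs.
* Mixture likelihoods, posteriors and BIC are computed in log space with
  `logsumexp`; the responsibilities of every droplet sum to 1 within 1e-9.
* NF is undefined (NA) at IR + ER = 0; such barcodes stay `unassigned`.
* Ties in the majority junction policy resolve to intronic.
* The droplet-table TSV writes NF with 6 significant digits and `NA` for
  undefined values.
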