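"""Readers and writers for the tool's tabular interfaces.

Barcode lists follow the Cell Ranger ``barcodes.tsv(.gz)`` dialect (one
barcode per line).  UMI totals come either from a two-column TSV or from a
MatrixMarket count-matrix directory by column-summing.  The droplet table is
a plain TSV round-tripped by ``read_droplet_table``/``write_droplet_table``.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from scipy.io import mmread

from .counting import STATUS_UNASSIGNED

__all__ = [
    "read_barcodes",
    "read_umi_counts",
    "read_droplet_table",
    "write_droplet_table",
]

DROPLET_COLUMNS = [
    "barcode",
    "intronic_reads",
    "exonic_reads",
    "nuclear_fraction",
    "umi_count",
    "cell_type",
    "qc_status",
]


def read_barcodes(path) -> list[str]:
    """One barcode per line, plain or gzipped; blank lines ignored."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    if not barcodes:
        raise ValueError(f"{path}: no barcodes found")
    return barcodes


def read_umi_counts(path) -> pd.Series:
    """Per-barcode UMI totals.

    ``path`` is either a two-column TSV (barcode, umi_count; a header line
    is detected and skipped) or a Cell Ranger-style matrix directory holding
    ``matrix.mtx(.gz)`` and ``barcodes.tsv(.gz)``, in which case totals are
    the per-column sums of the count matrix.
    """
    path = Path(path)
    if path.is_dir():
        mtx = _find_one(path, ("matrix.mtx", "matrix.mtx.gz"))
        bcs = _find_one(path, ("barcodes.tsv", "barcodes.tsv.gz"))
        matrix = mmread(str(mtx)).tocsc()
        barcodes = read_barcodes(bcs)
        if matrix.shape[1] != len(barcodes):
            raise ValueError(
                f"{path}: matrix has {matrix.shape[1]} columns but "
                f"{len(barcodes)} barcodes"
            )
        totals = matrix.sum(axis=0).A1
        return pd.Series(totals.astype(int), index=barcodes, name="umi_count")
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (barcode, umi_count)")
    # tolerate a header row
    first = str(df.iloc[0, 1])
    if not first.lstrip("-").isdigit():
        df = df.iloc[1:]
    return pd.Series(
        df.iloc[:, 1].astype(int).values, index=df.iloc[:, 0].astype(str).values,
        name="umi_count",
    )


def _find_one(directory: Path, names) -> Path:
    for name in names:
        candidate = directory / name
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"none of {names} found in {directory}")


def write_droplet_table(table: pd.DataFrame, path) -> None:
    """Write the droplet table as TSV; NF with 6 significant digits, NaN→NA."""
    out = table.copy()
    for col in DROPLET_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA if col == "cell_type" else (
                STATUS_UNASSIGNED if col == "qc_status" else 0
            )
    out = out[DROPLET_COLUMNS]
    out["nuclear_fraction"] = out["nuclear_fraction"].map(
        lambda v: "NA" if pd.isna(v) else f"{v:.6g}"
    )
    out["cell_type"] = out["cell_type"].fillna("NA")
    out.to_csv(path, sep="\t", index=False)


def read_droplet_table(path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=True,
        dtype={"barcode": str},
    )
    missing = {"barcode", "nuclear_fraction"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if "umi_count" not in table.columns:
        table["umi_count"] = 0
    if "cell_type" not in table.columns:
        table["cell_type"] = pd.NA
    if "qc_status" not in table.columns:
        table["qc_status"] = STATUS_UNASSIGNED
    return table
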