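"""Readers and writers for the package's external formats.

* Drop-seq-style dense digital-gene-expression (DGE) TSV: first column
  ``GENE``, one column per cell barcode, integer counts.
* MatrixMarket triplet (``matrix.mtx``) with ``genes.tsv`` / ``barcodes.tsv``
  sidecar files, one identifier per line.
* Cohort tables and long-format percentile reference tables as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_dge", "write_dge",
    "read_mtx", "write_mtx",
    "read_cohort", "write_cohort",
    "read_reference_table",
]

COHORT_BASE_COLUMNS = ["subject_id", "group", "lh_day", "dct_scara5", "dct_dio2"]


def read_dge(path) -> pd.DataFrame:
    """Read a dense DGE TSV into a genes x cells integer DataFrame."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "GENE":
        raise ValueError(f"{path}: first column must be 'GENE', got "
                         f"{df.columns[0]!r}")
    df = df.set_index("GENE")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate gene or barcode identifiers")
    out = df.astype(np.int64)
    if (out.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return out


def write_dge(m: pd.DataFrame, path) -> None:
    out = m.copy()
    out.index.name = "GENE"
    out.to_csv(path, sep="\t")


def read_mtx(directory) -> pd.DataFrame:
    """Read ``matrix.mtx`` + ``genes.tsv`` / ``barcodes.tsv`` sidecars."""
    d = Path(directory)
    mat = spio.mmread(d / "matrix.mtx").toarray().astype(np.int64)
    genes = (d / "genes.tsv").read_text().split()
    barcodes = (d / "barcodes.tsv").read_text().split()
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"{d}: matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(barcodes)} barcodes)")
    return pd.DataFrame(mat, index=genes, columns=barcodes)


def write_mtx(m: pd.DataFrame, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(d / "matrix.mtx", sparse.coo_matrix(m.to_numpy()))
    (d / "genes.tsv").write_text("\n".join(map(str, m.index)) + "\n")
    (d / "barcodes.tsv").write_text("\n".join(map(str, m.columns)) + "\n")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV (subject rows with dCt values and image counts)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COHORT_BASE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_reference_table(path) -> pd.DataFrame:
    """Read a long-format percentile reference TSV
    (subject_id, lh_day, gene, dct)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"subject_id", "lh_day", "gene", "dct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
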