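"""Readers and writers for the pipeline's on-disk formats.

Matrices are stored either as MatrixMarket (``.mtx`` plus ``genes.tsv`` /
``cells.tsv`` label files) or as dense TSV with gene rows and cell columns;
gene annotations, metadata and result tables are CSV/TSV.  All matrix
artifacts are written genes-as-rows, cells-as-columns.  Round-trips are
lossless on values and labels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .qc import ANNOTATION_COLUMNS, CountMatrix, make_gene_annotation
from .tcr import CHAINS, CLONE_COLUMNS

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_clone_table",
    "write_clone_table",
]


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, index=True)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, index_col="gene_id")
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"{path}: annotation lacks columns {missing}")
    return make_gene_annotation(
        ann.index,
        symbols=ann["symbol"],
        biotype=list(ann["biotype"]),
        mito=ann.index[ann["mito"].astype(bool)],
        ribo=ann.index[ann["ribo"].astype(bool)],
        y_chr=ann.index[ann["y_chr"].astype(bool)],
        spikein=ann.index[ann["spikein"].astype(bool)],
    )


def write_matrix(matrix: CountMatrix, path, fmt: str = "mtx") -> None:
    """Write a matrix as ``<path>.mtx`` + label TSVs (``fmt="mtx"``) or as a
    single dense TSV (``fmt="tsv"``); the annotation goes to
    ``<path>.genes.csv`` either way."""
    path = Path(path)
    if fmt == "mtx":
        scipy.io.mmwrite(str(path.with_suffix(".mtx")), scipy.sparse.csr_matrix(matrix.values))
        path.with_suffix(".cells.tsv").write_text("\n".join(matrix.cells) + "\n")
        path.with_suffix(".rows.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
    elif fmt == "tsv":
        df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.cells)
        df.to_csv(path.with_suffix(".tsv"), sep="\t")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    write_annotation(matrix.genes, path.with_suffix(".genes.csv"))


def read_matrix(path, fmt: str = "mtx", signed: bool = False) -> CountMatrix:
    path = Path(path)
    ann = read_annotation(path.with_suffix(".genes.csv"))
    if fmt == "mtx":
        values = np.asarray(scipy.io.mmread(str(path.with_suffix(".mtx"))).todense())
        cells = path.with_suffix(".cells.tsv").read_text().splitlines()
        genes = path.with_suffix(".rows.tsv").read_text().splitlines()
        if list(ann.index) != genes:
            raise ValueError(f"{path}: annotation order disagrees with rows.tsv")
    elif fmt == "tsv":
        df = pd.read_csv(path.with_suffix(".tsv"), sep="\t", index_col=0)
        values, cells = df.to_numpy(float), list(df.columns)
        ann = ann.loc[df.index]
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    return CountMatrix(values, ann, pd.Index(cells, name="cell_id"), signed=signed)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index=True)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col=0)
    meta.index.name = "cell_id"
    return meta


def write_clone_table(records: pd.DataFrame, path) -> None:
    records[CLONE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clone_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a MiXCR-export-style clone TSV.

    ``column_map`` renames source columns to the canonical
    ``cell_id, chain, cdr3_nt, cdr3_aa, read_count`` schema.  Malformed rows
    are reported with their line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CLONE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: clone table lacks columns {missing}")
    df = df[CLONE_COLUMNS]
    bad = ~df["chain"].isin(CHAINS)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # 1-based incl. header
        raise ValueError(f"{path}: unknown chain symbol at lines {rows}")
    counts = pd.to_numeric(df["read_count"], errors="coerce")
    if counts.isna().any() or (counts < 1).any():
        rows = (df.index[counts.isna() | (counts < 1)] + 2).tolist()
        raise ValueError(f"{path}: invalid read counts at lines {rows}")
    df["read_count"] = counts.astype(int)
    return df
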