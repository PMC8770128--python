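"""Readers and writers for the formats the pipeline touches.

Barcode reads travel as FASTQ (cell barcode and UMI carried in the read id)
or as a 4-column TSV dialect (cell_barcode, umi, payload, read_count);
expression matrices as MatrixMarket directories (matrix.mtx + barcodes.tsv
+ features.tsv, genes x cells as produced by droplet pipelines) or dense
CSV (cells x genes); tables as comma-separated UTF-8 CSV with a header row
and no index column.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .synthetic import ReadSet

READS_COLUMNS = ["cell_barcode", "umi", "payload", "read_count"]


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def write_reads_tsv(readset: ReadSet, path: str | Path) -> None:
    readset.to_frame().to_csv(path, sep="\t", index=False)


def write_reads_fastq(readset: ReadSet, path: str | Path) -> None:
    """One FASTQ entry per PCR duplicate; id = r<rec>_<dup> CB:<cb> UMI:<umi>."""
    with open(path, "w") as fh:
        for i, (cb, umi, payload, count) in enumerate(readset.records):
            for j in range(count):
                fh.write(f"@r{i:07d}_{j} CB:{cb} UMI:{umi}\n")
                fh.write(payload + "\n+\n" + "I" * len(payload) + "\n")


def read_reads(path: str | Path, format: str = "tsv") -> ReadSet:
    """Parse a reads file into a ReadSet.

    FASTQ PCR duplicates (same record id stem, cell barcode and UMI) are
    re-aggregated into read counts. Malformed records raise with the record
    index; an empty file yields an empty ReadSet.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in READS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"reads TSV lacks columns: {missing}")
        bad = df["read_count"].isna() | (df["read_count"] < 1)
        if bad.any():
            raise ValueError(
                f"malformed read_count at data row {int(np.flatnonzero(bad)[0])}"
            )
        records = [
            (str(r.cell_barcode), str(r.umi), str(r.payload), int(r.read_count))
            for r in df.itertuples(index=False)
        ]
        return ReadSet(records=records, mode="unknown", cell_barcode_of={})
    if format == "fastq":
        counts: dict[tuple[str, str, str], int] = {}
        order: list[tuple[str, str, str]] = []
        try:
            for idx, rec in enumerate(SeqIO.parse(str(path), "fastq")):
                tags = dict(
                    t.split(":", 1) for t in rec.description.split()[1:] if ":" in t
                )
                if "CB" not in tags or "UMI" not in tags:
                    raise ValueError(f"record {idx} lacks CB/UMI tags: {rec.id}")
                key = (tags["CB"], tags["UMI"], str(rec.seq))
                if key not in counts:
                    counts[key] = 0
                    order.append(key)
                counts[key] += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ near record {len(order)}: {exc}") from exc
        records = [(cb, umi, pl, counts[(cb, umi, pl)]) for cb, umi, pl in order]
        return ReadSet(records=records, mode="unknown", cell_barcode_of={})
    raise ValueError(f"unknown reads format: {format!r}")


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def write_matrix_mtx(
    expr: pd.DataFrame, directory: str | Path
) -> None:
    """Write a cells x genes frame as an MTX directory (genes x cells)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = csr_matrix(expr.to_numpy().T)
    mmwrite(str(directory / "matrix.mtx"), mat)
    pd.Series(expr.index).to_csv(directory / "barcodes.tsv", index=False, header=False)
    pd.Series(expr.columns).to_csv(directory / "features.tsv", index=False, header=False)


def read_matrix(path: str | Path, format: str = "mtx_dir") -> pd.DataFrame:
    """Read an expression matrix as a cells x genes DataFrame.

    ``mtx_dir`` expects matrix.mtx (genes x cells) with barcodes.tsv and
    features.tsv; ``csv`` expects a dense cells x genes table with the cell
    id in the first column. Dimension mismatches, duplicated names and
    empty matrices are errors.
    """
    path = Path(path)
    if format == "mtx_dir":
        mat = mmread(str(path / "matrix.mtx"))
        barcodes = pd.read_csv(path / "barcodes.tsv", header=None)[0].astype(str)
        features = pd.read_csv(path / "features.tsv", header=None)[0].astype(str)
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        if dense.shape != (len(features), len(barcodes)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match "
                f"{len(features)} features x {len(barcodes)} barcodes"
            )
        df = pd.DataFrame(dense.T, index=barcodes, columns=features)
    elif format == "csv":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
        if len(set(header)) != len(header):
            dupes = sorted({g for g in header if header.count(g) > 1})
            raise ValueError(f"duplicated gene names: {dupes[:3]}")
        df = pd.read_csv(path, index_col=0)
    else:
        raise ValueError(f"unknown matrix format: {format!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("empty expression matrix")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicated gene names: {dupes[:3]}")
    if df.index.duplicated().any():
        raise ValueError("duplicated cell names")
    return df


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """CSV writer with an optional '# key=value' metadata comment block."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if metadata:
            for k in sorted(metadata):
                fh.write(f"# {k}={metadata[k]}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`, returning (frame, metadata)."""
    meta: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if line.startswith("# ") and "=" in line:
            k, v = line[2:].strip().split("=", 1)
            meta[k] = v
            body_start += 1
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    return df, meta
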