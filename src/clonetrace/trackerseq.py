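"""TrackerSeq transposon-barcode processing.

Cells carry multiple genomic integrations of a 37-nt lineage barcode, so a
clone is identified by a shared *set* of barcodes rather than a single one.
Reads are filtered at the triple level (cell-UMI-barcode, >= 10 reads) and
pair level (cell-barcode, >= 6 distinct UMIs) into a binary integration
matrix; clones are the flat clusters of an average-linkage dendrogram over
Jaccard distances between the rows, cut at height 0.999 so that only cells
sharing at least some integrations can merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .sticr import CloneTable, SticrParams, _collapse_umis


@dataclass(frozen=True)
class TrackerParams:
    min_reads_per_triple: int = 10
    min_umi_per_pair: int = 6
    linkage: str = "average"
    cut_height: float = 0.999
    min_barcode_length: int = 37
    umi_collapse_mismatch: int = 0  # no mismatch allowance in this assay
    barcode_precollapse_mismatch: int = 0  # optional Hamming pre-collapse, off

    def __post_init__(self):
        if min(self.min_reads_per_triple, self.min_umi_per_pair, self.min_barcode_length) < 1:
            raise ValueError("thresholds must be positive")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must lie in (0, 1]")


@dataclass
class IntegrationMatrix:
    """Binary cells x lineage-barcodes presence matrix after filtering."""

    cells: list[str]
    barcodes: list[str]
    entries: np.ndarray  # bool, shape (n_cells, n_barcodes)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=bool)
        if self.entries.shape != (len(self.cells), len(self.barcodes)):
            raise ValueError("matrix shape does not match the name lists")
        if len(self.cells) and not self.entries.any(axis=1).all():
            raise ValueError("all-zero rows are not allowed after filtering")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries.astype(int), index=self.cells, columns=self.barcodes
        )

    @classmethod
    def from_sets(cls, sets: dict[str, frozenset[str] | set[str]]) -> "IntegrationMatrix":
        cells = sorted(sets)
        barcodes = sorted({b for s in sets.values() for b in s})
        col = {b: j for j, b in enumerate(barcodes)}
        entries = np.zeros((len(cells), len(barcodes)), dtype=bool)
        for i, c in enumerate(cells):
            for b in sets[c]:
                entries[i, col[b]] = True
        return cls(cells=cells, barcodes=barcodes, entries=entries)


def _precollapse_barcodes(
    reads: pd.DataFrame, max_mismatch: int
) -> pd.DataFrame:
    """Optional greedy Hamming collapse of barcode sequencing errors into the
    most-read barcode of each cluster (off by default)."""
    counts = reads.groupby("barcode")["read_count"].sum().to_dict()
    by_len: dict[int, dict[str, int]] = {}
    for bc, n in counts.items():
        by_len.setdefault(len(bc), {})[bc] = int(n)
    remap: dict[str, str] = {}
    for group in by_len.values():
        survivors = _collapse_umis(group, max_mismatch)
        surv_set = sorted(survivors, key=lambda b: (-group[b], b))
        enc = {b: np.frombuffer(b.encode(), dtype=np.uint8) for b in group}
        for bc in group:
            if bc in survivors:
                remap[bc] = bc
                continue
            best = min(
                surv_set,
                key=lambda s: ((enc[bc] != enc[s]).sum(), s),
            )
            remap[bc] = best
    out = reads.copy()
    out["barcode"] = out["barcode"].map(remap)
    return out


def filter_integrations(
    records: pd.DataFrame | list[tuple[str, str, str, int]],
    params: TrackerParams = TrackerParams(),
) -> IntegrationMatrix:
    """Build the binary integration matrix from (cell, umi, barcode, read_count).

    Barcodes shorter than ``min_barcode_length`` are discarded (counted in
    diagnostics); a triple survives with >= ``min_reads_per_triple`` reads;
    a (cell, barcode) pair becomes a matrix entry with >=
    ``min_umi_per_pair`` surviving distinct UMIs. An empty result is
    returned with diagnostics, not raised.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            records, columns=["cell", "umi", "barcode", "read_count"]
        )
    records = records[["cell", "umi", "barcode", "read_count"]].copy()
    diag = {"records_in": len(records), "reads_in": int(records["read_count"].sum())}

    ok_len = records["barcode"].str.len() >= params.min_barcode_length
    diag["barcodes_too_short"] = int((~ok_len).sum())
    records = records[ok_len]

    if params.barcode_precollapse_mismatch > 0 and len(records):
        records = _precollapse_barcodes(records, params.barcode_precollapse_mismatch)

    triples = (
        records.groupby(["cell", "umi", "barcode"], sort=True)["read_count"]
        .sum()
        .reset_index()
    )
    diag["triples_in"] = len(triples)
    triples = triples[triples["read_count"] >= params.min_reads_per_triple]
    diag["triples_kept"] = len(triples)

    if params.umi_collapse_mismatch > 0 and len(triples):
        kept = []
        for (cell, bc), grp in triples.groupby(["cell", "barcode"], sort=True):
            counts = dict(zip(grp["umi"], grp["read_count"]))
            kept.append((cell, bc, len(_collapse_umis(counts, params.umi_collapse_mismatch))))
        pairs = pd.DataFrame(kept, columns=["cell", "barcode", "n_umi"])
    else:
        pairs = (
            triples.groupby(["cell", "barcode"], sort=True)["umi"]
            .nunique()
            .reset_index(name="n_umi")
        )
    pairs = pairs[pairs["n_umi"] >= params.min_umi_per_pair]
    diag["pairs_kept"] = len(pairs)

    if pairs.empty:
        out = IntegrationMatrix(cells=[], barcodes=[], entries=np.zeros((0, 0), bool))
        out.diagnostics = diag
        return out
    sets = {
        str(cell): set(grp["barcode"]) for cell, grp in pairs.groupby("cell", sort=True)
    }
    out = IntegrationMatrix.from_sets(sets)
    diag["cells_kept"] = len(out.cells)
    diag["barcodes_kept"] = len(out.barcodes)
    out.diagnostics = diag
    return out


def jaccard_distances(matrix: IntegrationMatrix) -> np.ndarray:
    """Condensed 1 - Jaccard distance vector between matrix rows."""
    return pdist(matrix.entries, metric="jaccard")


def call_clones_jaccard(
    matrix: IntegrationMatrix,
    params: TrackerParams = TrackerParams(),
    dataset: str = "ds0",
) -> CloneTable:
    """Clone assignment by average-linkage clustering of Jaccard distances.

    The dendrogram is cut at ``cut_height`` on the distance scale: cells
    merge into one clone only through merge heights below the cut, so
    groups sharing no barcode (distance exactly 1) never join.
    """
    if len(matrix.cells) == 0:
        raise ValueError("empty integration matrix")
    if len(matrix.cells) == 1:
        labels = np.array([1])
    else:
        Z = linkage(jaccard_distances(matrix), method=params.linkage)
        labels = fcluster(Z, t=params.cut_height, criterion="distance")
    clones: dict[str, set[str]] = {}
    for cell, lab in zip(matrix.cells, labels):
        clones.setdefault(f"{dataset}:tclone{int(lab):05d}", set()).add(cell)
    return CloneTable(
        clones={k: frozenset(v) for k, v in clones.items()},
        dataset_of={k: dataset for k in clones},
        barcode_of={k: k.split(":", 1)[1] for k in clones},
    )


def integration_stats(
    matrix: IntegrationMatrix, subset: set[str] | list[str] | None = None
) -> dict:
    """Cell/barcode totals and the fractions of cells with >= 2 and >= 5
    integrations (row sums), optionally restricted to a cell subset."""
    if subset is not None:
        subset = set(subset)
        missing = subset - set(matrix.cells)
        if missing:
            raise ValueError(f"subset cells not in matrix: {sorted(missing)[:3]}")
        if not subset:
            raise ValueError("empty subset")
        rows = np.array([c in subset for c in matrix.cells])
    else:
        rows = np.ones(len(matrix.cells), dtype=bool)
    if not rows.any():
        raise ValueError("no cells selected")
    sums = matrix.entries[rows].sum(axis=1)
    cols = matrix.entries[rows].any(axis=0)
    return {
        "n_cells": int(rows.sum()),
        "n_barcodes": int(cols.sum()),
        "frac_ge2": float((sums >= 2).mean()),
        "frac_ge5": float((sums >= 5).mean()),
    }


def multicellular_clones(
    table: CloneTable, subset: set[str] | list[str] | None = None
) -> int:
    """Number of clones with >= 2 cells, after optional restriction of each
    clone to an annotated cell subset (restriction precedes sizing)."""
    n = 0
    subset = set(subset) if subset is not None else None
    for cells in table.clones.values():
        kept = cells if subset is None else cells & subset
        if len(kept) >= 2:
            n += 1
    return n
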