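"""STICR combinatorial-barcode processing: fragment alignment, UMI
deduplication, tiered dominant-barcode assignment and clone tables.

The clonal barcode of a cell is a triple of fragments, each aligned to its
reference pool with up to two mismatches, plus an exactly matching viral
index. Reads are collapsed to distinct UMIs (1-mismatch directional
collapse), barcode candidacy requires >= 5 distinct UMIs, a multi-candidate
cell needs a 5x dominant barcode (tier 2; a single candidate is tier 1),
and any call used for clonal analysis needs >= 9 distinct UMIs. Cells
sharing a barcode within a dataset form a clone; barcodes seen in more
than one dataset are blacklisted as suspected library collisions.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import BarcodeLibrary


@dataclass(frozen=True)
class SticrParams:
    max_fragment_mismatch: int = 2
    umi_collapse_mismatch: int = 1
    min_umi_candidate: int = 5
    dominance_factor: float = 5.0
    min_umi_final: int = 9

    def __post_init__(self):
        if min(
            self.max_fragment_mismatch,
            self.umi_collapse_mismatch,
            self.min_umi_candidate,
            self.min_umi_final,
        ) < 0 or self.dominance_factor < 0:
            raise ValueError("parameters must be non-negative")
        if self.min_umi_final < self.min_umi_candidate:
            raise ValueError("min_umi_final must be >= min_umi_candidate")


@dataclass(frozen=True)
class ReadLayout:
    """Fixed offsets of the three fragments and viral index in a payload."""

    fragment_length: int = 14
    viral_index_length: int = 6
    start: int = 0

    @property
    def span(self) -> int:
        return 3 * self.fragment_length + self.viral_index_length

    def slices(self):
        L, s = self.fragment_length, self.start
        return [
            slice(s, s + L),
            slice(s + L, s + 2 * L),
            slice(s + 2 * L, s + 3 * L),
            slice(s + 3 * L, s + 3 * L + self.viral_index_length),
        ]


@dataclass(frozen=True)
class BarcodeCall:
    cell_id: str
    barcode_id: str
    umi_count: int
    tier: int
    dataset: str = "ds0"


@dataclass
class CloneTable:
    """Partition of cells into clones; the unit of all lineage statistics."""

    clones: dict[str, frozenset[str]]
    dataset_of: dict[str, str]
    barcode_of: dict[str, str]

    def __post_init__(self):
        seen: set[str] = set()
        for cid, cells in self.clones.items():
            if not cells:
                raise ValueError(f"clone {cid} is empty")
            if seen & cells:
                raise ValueError("clones must be disjoint")
            seen |= cells

    @property
    def cells(self) -> list[str]:
        return sorted(c for cells in self.clones.values() for c in cells)

    def clone_of(self) -> dict[str, str]:
        return {c: cid for cid, cells in self.clones.items() for c in cells}

    def sizes(self) -> pd.Series:
        return pd.Series({cid: len(cells) for cid, cells in self.clones.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cell, cid, self.dataset_of[cid])
            for cid, cells in self.clones.items()
            for cell in sorted(cells)
        ]
        return pd.DataFrame(rows, columns=["cell", "clone", "dataset"])

    @classmethod
    def from_clone_map(cls, clone_of: dict[str, str], dataset: str = "ds0") -> "CloneTable":
        """Build a table from a cell -> clone mapping (e.g. simulation truth)."""
        clones: dict[str, set[str]] = defaultdict(set)
        for cell, cid in clone_of.items():
            clones[cid].add(cell)
        return cls(
            clones={k: frozenset(v) for k, v in clones.items()},
            dataset_of={k: dataset for k in clones},
            barcode_of={k: k for k in clones},
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CloneTable":
        clones: dict[str, set[str]] = defaultdict(set)
        dataset_of: dict[str, str] = {}
        for row in df.itertuples(index=False):
            clones[row.clone].add(row.cell)
            dataset_of[row.clone] = getattr(row, "dataset", "ds0")
        return cls(
            clones={k: frozenset(v) for k, v in clones.items()},
            dataset_of=dataset_of,
            barcode_of={k: k for k in clones},
        )


@dataclass(frozen=True)
class FragmentReference:
    """Reference fragment pools plus the known viral index sequences."""

    pools: tuple[tuple[str, ...], ...]
    viral_indices: tuple[str, ...]

    def __post_init__(self):
        for pool in self.pools:
            if len(set(pool)) != len(pool):
                raise ValueError("pool sequences must be distinct")
            if len({len(s) for s in pool}) != 1:
                raise ValueError("pool sequences must have equal length")

    @classmethod
    def from_library(cls, library: BarcodeLibrary) -> "FragmentReference":
        return cls(pools=library.pools, viral_indices=(library.viral_index,))


# ---------------------------------------------------------------------------
# Fragment extraction and alignment
# ---------------------------------------------------------------------------


def extract_fragments(read: str, layout: ReadLayout):
    """Substrings (frag1, frag2, frag3, viral_index) at the layout offsets.

    Returns ``(None, "truncated")`` if the read is shorter than the layout
    span; flanking sequence outside the offsets is ignored.
    """
    if len(read) < layout.start + layout.span:
        return None, "truncated"
    s1, s2, s3, si = layout.slices()
    return (read[s1], read[s2], read[s3], read[si]), None


def _encode_pool(pool: tuple[str, ...]) -> np.ndarray:
    return np.frombuffer("".join(pool).encode(), dtype=np.uint8).reshape(
        len(pool), len(pool[0])
    )


def align_fragment(seq: str, pool: tuple[str, ...], params: SticrParams = SticrParams()):
    """Unique pool entry within ``max_fragment_mismatch`` of ``seq``.

    Returns the fragment index, or ``"none"`` if nothing qualifies, or
    ``"ambiguous"`` if two or more entries tie at the minimum qualifying
    distance. A length mismatch is an error, not a non-match.
    """
    if len(seq) != len(pool[0]):
        raise ValueError("query length does not match pool fragment length")
    enc = _encode_pool(pool)
    q = np.frombuffer(seq.encode(), dtype=np.uint8)
    d = (enc != q).sum(axis=1)
    dmin = int(d.min())
    if dmin > params.max_fragment_mismatch:
        return "none"
    hits = np.flatnonzero(d == dmin)
    return int(hits[0]) if len(hits) == 1 else "ambiguous"


def _align_batch(seqs: list[str], pool: tuple[str, ...], max_mm: int) -> np.ndarray:
    """Vectorized alignment of many equal-length queries; -1 none, -2 ambiguous."""
    enc = _encode_pool(pool)
    q = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), len(pool[0])
    )
    d = (q[:, None, :] != enc[None, :, :]).sum(axis=2)  # (n, pool)
    dmin = d.min(axis=1)
    best = d.argmin(axis=1)
    ties = (d == dmin[:, None]).sum(axis=1) > 1
    out = np.where(dmin <= max_mm, best, -1)
    out[ties & (dmin <= max_mm)] = -2
    return out


# ---------------------------------------------------------------------------
# UMI deduplication
# ---------------------------------------------------------------------------


def _collapse_umis(counts: dict[str, int], max_mismatch: int) -> list[str]:
    """Directional collapse: absorb lower-count UMIs within Hamming distance
    of a cluster member, seeds visited by (count desc, lexicographic)."""
    if max_mismatch == 0:
        return sorted(counts)
    order = sorted(counts, key=lambda u: (-counts[u], u))
    enc = np.frombuffer("".join(order).encode(), dtype=np.uint8).reshape(
        len(order), len(order[0])
    )
    dist = (enc[:, None, :] != enc[None, :, :]).sum(axis=2)
    assigned = np.zeros(len(order), dtype=bool)
    survivors = []
    for i in range(len(order)):
        if assigned[i]:
            continue
        assigned[i] = True
        survivors.append(order[i])
        frontier = [i]
        while frontier:
            j = frontier.pop()
            nb = np.flatnonzero((dist[j] <= max_mismatch) & ~assigned)
            # directional: only absorb neighbours with count <= the member's
            nb = [k for k in nb if counts[order[k]] <= counts[order[j]]]
            for k in nb:
                assigned[k] = True
                frontier.append(k)
    return survivors


def dedup_umis(
    triples: list[tuple[str, str, str, int]] | pd.DataFrame,
    params: SticrParams = SticrParams(),
) -> pd.DataFrame:
    """Distinct-UMI counts per (cell, barcode) after directional collapse.

    ``triples`` rows are (cell_id, umi, barcode_id, read_count). UMIs within
    ``umi_collapse_mismatch`` of a higher-count UMI merge into it (ties
    broken lexicographically); the returned ``umi_count`` is the number of
    surviving UMIs.
    """
    if isinstance(triples, pd.DataFrame):
        rows = list(
            triples[["cell_id", "umi", "barcode_id", "read_count"]].itertuples(
                index=False, name=None
            )
        )
    else:
        rows = list(triples)
    groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for cell, umi, bc, n in rows:
        groups[(cell, bc)][umi] += int(n)
    out = []
    for (cell, bc), counts in sorted(groups.items()):
        lengths = {len(u) for u in counts}
        if len(lengths) > 1:
            raise ValueError(f"unequal UMI lengths for cell {cell}")
        out.append((cell, bc, len(_collapse_umis(counts, params.umi_collapse_mismatch))))
    return pd.DataFrame(out, columns=["cell_id", "barcode_id", "umi_count"])


# ---------------------------------------------------------------------------
# Dominant-barcode assignment and clone building
# ---------------------------------------------------------------------------


def assign_clonal_barcode(
    cell_counts: dict[str, int],
    params: SticrParams = SticrParams(),
    cell_id: str = "",
    dataset: str = "ds0",
) -> BarcodeCall | None:
    """Tiered clonal-barcode decision for one cell.

    Candidates are barcodes with >= ``min_umi_candidate`` distinct UMIs.
    Exactly one candidate -> tier 1. Two or more -> tier 2 iff the top
    candidate has >= ``dominance_factor`` times the UMIs of the next most
    abundant barcode. The winning call is kept only with >=
    ``min_umi_final`` UMIs; every other path returns None.
    """
    if any(v <= 0 for v in cell_counts.values()):
        raise ValueError("UMI counts must be positive")
    ranked = sorted(cell_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    candidates = [(b, n) for b, n in ranked if n >= params.min_umi_candidate]
    if not candidates:
        return None
    if len(candidates) == 1:
        barcode, n = candidates[0]
        tier = 1
    else:
        barcode, n = candidates[0]
        runner_up = ranked[1][1]
        if n < params.dominance_factor * runner_up:
            return None
        tier = 2
    if n < params.min_umi_final:
        return None
    return BarcodeCall(cell_id=cell_id, barcode_id=barcode, umi_count=n, tier=tier, dataset=dataset)


def build_clone_table(
    calls: list[BarcodeCall], tier_policy: str = "tier1_only"
) -> CloneTable:
    """Group cells sharing a barcode within a dataset into clones.

    Barcodes observed in two or more datasets are blacklisted (suspected
    library collisions) and all their cells dropped. ``tier_policy`` is
    ``"tier1_only"`` (the default used for clonal analysis) or
    ``"tier1_and_2"``.
    """
    if tier_policy not in ("tier1_only", "tier1_and_2"):
        raise ValueError(f"unknown tier policy: {tier_policy!r}")
    seen_cells: dict[str, str] = {}
    for c in calls:
        prev = seen_cells.get(c.cell_id)
        if prev is not None and prev != c.barcode_id:
            raise ValueError(f"conflicting barcode calls for cell {c.cell_id}")
        seen_cells[c.cell_id] = c.barcode_id
    kept = [c for c in calls if c.tier == 1 or tier_policy == "tier1_and_2"]
    datasets_of_barcode: dict[str, set[str]] = defaultdict(set)
    for c in kept:
        datasets_of_barcode[c.barcode_id].add(c.dataset)
    blacklist = {b for b, ds in datasets_of_barcode.items() if len(ds) > 1}
    clones: dict[str, set[str]] = defaultdict(set)
    dataset_of: dict[str, str] = {}
    barcode_of: dict[str, str] = {}
    for c in kept:
        if c.barcode_id in blacklist:
            continue
        cid = f"{c.dataset}:{c.barcode_id}"
        clones[cid].add(c.cell_id)
        dataset_of[cid] = c.dataset
        barcode_of[cid] = c.barcode_id
    return CloneTable(
        clones={k: frozenset(v) for k, v in clones.items()},
        dataset_of=dataset_of,
        barcode_of=barcode_of,
    )


def clone_size_summary(table: CloneTable) -> pd.DataFrame:
    """Per-dataset mean, s.e.m. and max of multicellular clone sizes.

    Multicellular means >= 2 cells; singleton clones are counted separately.
    """
    if not table.clones:
        raise ValueError("empty clone table")
    rows = []
    by_ds: dict[str, list[int]] = defaultdict(list)
    for cid, cells in table.clones.items():
        by_ds[table.dataset_of[cid]].append(len(cells))
    for ds, sizes in sorted(by_ds.items()):
        multi = np.array([s for s in sizes if s >= 2])
        n_single = sum(1 for s in sizes if s == 1)
        if len(multi):
            sem = float(np.std(multi, ddof=1) / np.sqrt(len(multi))) if len(multi) > 1 else 0.0
            rows.append((ds, len(multi), n_single, float(multi.mean()), sem, int(multi.max())))
        else:
            rows.append((ds, 0, n_single, np.nan, np.nan, 0))
    return pd.DataFrame(
        rows,
        columns=["dataset", "n_multicellular", "n_singleton", "mean_size", "sem_size", "max_size"],
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def call_sticr_clones(
    records: list[tuple[str, str, str, int]] | pd.DataFrame,
    reference: FragmentReference,
    params: SticrParams = SticrParams(),
    layout: ReadLayout = ReadLayout(),
    dataset: str = "ds0",
    tier_policy: str = "tier1_only",
):
    """Full STICR pipeline on (cell_barcode, umi, payload, read_count) records.

    Returns ``(calls_df, clone_table, funnel)`` where ``funnel`` reports the
    record counts surviving each filter (extraction, fragment alignment,
    viral-index match, UMI thresholds).
    """
    if isinstance(records, pd.DataFrame):
        records = list(
            records[["cell_barcode", "umi", "payload", "read_count"]].itertuples(
                index=False, name=None
            )
        )
    funnel = {"reads_in": int(sum(r[3] for r in records)), "records_in": len(records)}

    extracted = []
    for cb, umi, payload, n in records:
        frags, reason = extract_fragments(payload, layout)
        if frags is None:
            continue
        extracted.append((cb, umi, frags, n))
    funnel["records_extracted"] = len(extracted)

    # viral index: exact match to a known index required
    vi_ok = [r for r in extracted if r[2][3] in reference.viral_indices]
    funnel["records_index_matched"] = len(vi_ok)

    # vectorized fragment alignment over unique fragment sequences per pool
    aligned_rows = []
    if vi_ok:
        frag_cols = list(zip(*[r[2][:3] for r in vi_ok]))
        maps = []
        for pi in range(3):
            uniq = sorted(set(frag_cols[pi]))
            res = _align_batch(uniq, reference.pools[pi], params.max_fragment_mismatch)
            maps.append(dict(zip(uniq, res)))
        for cb, umi, frags, n in vi_ok:
            ids = [maps[pi][frags[pi]] for pi in range(3)]
            if min(ids) < 0:  # none or ambiguous in any fragment -> drop read
                continue
            bc = "-".join(f"F{pi+1}_{ids[pi]:03d}" for pi in range(3))
            aligned_rows.append((cb, umi, bc, n))
    funnel["records_aligned"] = len(aligned_rows)

    counts = dedup_umis(
        [(cb, umi, bc, n) for cb, umi, bc, n in aligned_rows], params
    )
    calls = []
    for cell, grp in counts.groupby("cell_id", sort=True):
        cc = dict(zip(grp["barcode_id"], grp["umi_count"]))
        call = assign_clonal_barcode(cc, params, cell_id=str(cell), dataset=dataset)
        if call is not None:
            calls.append(call)
    funnel["cells_seen"] = counts["cell_id"].nunique()
    funnel["cells_called"] = len(calls)
    table = build_clone_table(calls, tier_policy=tier_policy)
    funnel["clones"] = len(table.clones)
    calls_df = pd.DataFrame(
        [(c.cell_id, c.barcode_id, c.umi_count, c.tier, c.dataset) for c in calls],
        columns=["cell", "barcode", "umi_count", "tier", "dataset"],
    )
    return calls_df, table, funnel
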