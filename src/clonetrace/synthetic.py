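"""Seeded generators for every input the lineage pipeline consumes.

The generators emulate the experimental design of combinatorial lineage
barcoding: a lentiviral library whose barcodes are three fragments drawn
from pools of distinct oligonucleotides (STICR-style), or a transposon
library whose 37-nt barcodes integrate in multiple genomic copies per cell
(TrackerSeq-style). Clonal populations carry ground truth (clone, state,
class per cell) so downstream clone calling and coupling statistics can be
validated against a known answer. Read sets add the noise the real
thresholds guard against: PCR duplicates, 1-substitution UMI errors and
<=2-substitution fragment errors.

Every generator is a pure function of its arguments including ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: 37-nt TrackerSeq barcode template: 8 blocks of 2 random positions ("N")
#: bridged by fixed trinucleotides -> 4**16 = 16**8 distinct barcodes.
DEFAULT_TRACKER_MASK = "NNGTCNNTAGNNCCANNGTTNNACGNNTGANNCATNN"

DEFAULT_FRAGMENT_LENGTH = 14
DEFAULT_UMI_LENGTH = 10
DEFAULT_CELL_BARCODE_LENGTH = 16


def _decode(row: np.ndarray) -> str:
    return row.tobytes().decode("ascii")


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """(n, length) uint8 array of ACGT codes."""
    return BASES[rng.integers(0, 4, size=(n, length))]


def _distinct_random_strings(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: dict[str, None] = {}
    while len(seen) < n:
        for row in _random_seqs(rng, n - len(seen), length):
            seen.setdefault(_decode(row), None)
    return list(seen)[:n]


# ---------------------------------------------------------------------------
# Barcode libraries
# ---------------------------------------------------------------------------


def combinatorial_diversity(pool_sizes: list[int] | tuple[int, ...]) -> int:
    """Theoretical number of distinct combinatorial barcodes.

    Three pools of 500 fragments give 500**3 = 125,000,000 combinations.
    """
    if not pool_sizes or any(s < 1 for s in pool_sizes):
        raise ValueError("pool_sizes must be positive")
    out = 1
    for s in pool_sizes:
        out *= int(s)
    return out


@dataclass(frozen=True)
class BarcodeLibrary:
    """Combinatorial fragment library for STICR-style barcodes.

    ``pools`` holds the fragment sequences per position; within a pool every
    pairwise Hamming distance is >= ``min_pairwise_hamming`` so that
    <=2-mismatch alignment is unambiguous. ``pool_weights`` are per-fragment
    sampling weights per pool (None = uniform); a combination's abundance is
    the product of its fragments' weights.
    """

    pools: tuple[tuple[str, ...], ...]
    viral_index: str
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH
    min_pairwise_hamming: int = 5
    pool_weights: tuple[tuple[float, ...], ...] | None = None

    @property
    def pool_sizes(self) -> tuple[int, ...]:
        return tuple(len(p) for p in self.pools)

    def diversity(self) -> int:
        return combinatorial_diversity(self.pool_sizes)

    def combination_sequence(self, combo: tuple[int, ...]) -> str:
        return "".join(self.pools[i][j] for i, j in enumerate(combo)) + self.viral_index


def _gen_pool(
    rng: np.random.Generator, size: int, length: int, min_dist: int
) -> tuple[str, ...]:
    """Greedy rejection sampling of ``size`` codes at pairwise Hamming >= min_dist."""
    accepted = np.empty((0, length), dtype=np.uint8)
    attempts = 0
    max_attempts = 2000 * size + 10000
    while len(accepted) < size:
        batch = _random_seqs(rng, 64, length)
        for cand in batch:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"cannot build a pool of {size} fragments of length {length} "
                    f"at pairwise Hamming distance >= {min_dist}"
                )
            if len(accepted) == 0 or (accepted != cand).sum(axis=1).min() >= min_dist:
                accepted = np.vstack([accepted, cand])
                if len(accepted) == size:
                    break
    return tuple(_decode(row) for row in accepted)


def gen_barcode_library(
    pool_sizes: list[int] | tuple[int, ...],
    abundance_model: str | tuple[str, float] = "uniform",
    seed: int = 0,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    min_pairwise_hamming: int = 5,
    viral_index_length: int = 6,
) -> BarcodeLibrary:
    """Generate a combinatorial fragment library.

    Parameters
    ----------
    pool_sizes
        Number of distinct fragments per pool (the study design uses three
        pools of 500, for 125 million combinations).
    abundance_model
        ``"uniform"`` or ``("lognormal", sigma)``: per-fragment lognormal
        weights model the abundance skew of a real plasmid library.
    """
    if not pool_sizes or any(s < 1 for s in pool_sizes):
        raise ValueError("pool_sizes must be positive")
    if fragment_length < min_pairwise_hamming:
        raise ValueError("fragment length shorter than the required Hamming separation")
    rng = np.random.default_rng(seed)
    pools = tuple(
        _gen_pool(rng, s, fragment_length, min_pairwise_hamming) for s in pool_sizes
    )
    weights: tuple[tuple[float, ...], ...] | None = None
    if abundance_model != "uniform":
        kind, sigma = abundance_model
        if kind != "lognormal" or sigma < 0:
            raise ValueError(f"unknown abundance model: {abundance_model!r}")
        weights = tuple(
            tuple(w / w.sum() for w in [rng.lognormal(0.0, sigma, size=s)])[0]
            for s in pool_sizes
        )
        weights = tuple(tuple(float(x) for x in w) for w in weights)
    viral_index = _decode(_random_seqs(rng, 1, viral_index_length)[0])
    return BarcodeLibrary(
        pools=pools,
        viral_index=viral_index,
        fragment_length=fragment_length,
        min_pairwise_hamming=min_pairwise_hamming,
        pool_weights=weights,
    )


# ---------------------------------------------------------------------------
# Clonal populations
# ---------------------------------------------------------------------------


@dataclass
class SimulatedPopulation:
    """Ground-truth clonal population.

    ``integrations`` maps each cell to its lineage tag: a tuple of fragment
    indices (one combinatorial barcode) in STICR mode, or a frozenset of
    37-nt barcode strings (genomic integrations) in TrackerSeq mode. All
    cells of a clone carry the identical tag.
    """

    cells: list[str]
    clone_of: dict[str, str]
    state_of: dict[str, str]
    class_of: dict[str, str]
    integrations: dict[str, tuple[int, ...] | frozenset[str]]
    mode: str  # "sticr" | "trackerseq"
    metadata: dict = field(default_factory=dict)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": self.cells,
                "clone": [self.clone_of[c] for c in self.cells],
                "state": [self.state_of[c] for c in self.cells],
                "class": [self.class_of[c] for c in self.cells],
            }
        )


def _draw_sizes(rng: np.random.Generator, n: int, spec) -> np.ndarray:
    kind = spec[0]
    if kind == "constant":
        return np.full(n, int(spec[1]))
    if kind == "geometric":
        # truncated geometric on 1..max: P(k) ~ (1-p)^(k-1)
        p, kmax = float(spec[1]), int(spec[2])
        ks = np.arange(1, kmax + 1)
        w = (1 - p) ** (ks - 1)
        return rng.choice(ks, size=n, p=w / w.sum())
    if kind == "poisson":
        # shifted so every clone has >= 1 cell
        return 1 + rng.poisson(float(spec[1]), size=n)
    if kind == "empirical":
        vals = np.asarray(spec[1], dtype=int)
        if len(vals) == 0 or (vals < 1).any():
            raise ValueError("empirical sizes must be positive")
        return rng.choice(vals, size=n)
    raise ValueError(f"unknown size distribution: {spec!r}")


def _clone_state_probs(rng, n_clones, states, state_probs) -> np.ndarray:
    S = len(states)
    if isinstance(state_probs, dict):
        state_probs = ("shared", state_probs)
    kind = state_probs[0]
    if kind == "shared":
        p = np.array([state_probs[1][s] for s in states], dtype=float)
        return np.tile(p / p.sum(), (n_clones, 1))
    if kind == "dirichlet":
        alpha = np.broadcast_to(np.asarray(state_probs[1], dtype=float), (S,))
        return rng.dirichlet(alpha, size=n_clones)
    if kind == "per_clone":
        mats = np.array(
            [[row[s] for s in states] for row in state_probs[1]], dtype=float
        )
        if mats.shape[0] != n_clones:
            raise ValueError("per_clone spec must list one distribution per clone")
        return mats / mats.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown state_probs spec: {state_probs!r}")


def _tracker_barcode(rng: np.random.Generator, mask: str) -> str:
    out = []
    for ch in mask:
        out.append("ACGT"[rng.integers(0, 4)] if ch == "N" else ch)
    return "".join(out)


def gen_clonal_population(
    n_clones: int,
    clone_size_dist=("geometric", 0.35, 30),
    states: list[str] = ("s1", "s2"),
    state_probs=("dirichlet", 1.0),
    mode: str = "sticr",
    integrations_per_cell_dist=("poisson", 3.0),
    seed: int = 0,
    pool_sizes: tuple[int, ...] = (500, 500, 500),
    class_of_state: dict[str, str] | None = None,
    tracker_mask: str = DEFAULT_TRACKER_MASK,
) -> SimulatedPopulation:
    """Generate a clonal population with recorded ground truth.

    Each clone's size comes from ``clone_size_dist`` and each of its cells
    draws a state from that clone's own state distribution, so low-
    concentration Dirichlet specs produce coherent clones and a shared
    distribution produces clone-independent labels (the permutation null).
    In STICR mode every clone carries one combinatorial barcode (distinct
    fragment-index triples across clones); in TrackerSeq mode every clone
    carries an identical set of integrations whose cardinality is drawn
    from ``integrations_per_cell_dist``.
    """
    if n_clones < 1:
        raise ValueError("need at least one clone")
    states = list(states)
    if not states:
        raise ValueError("state set must be non-empty")
    if mode not in ("sticr", "trackerseq"):
        raise ValueError(f"unknown mode: {mode!r}")
    rng = np.random.default_rng(seed)
    sizes = _draw_sizes(rng, n_clones, clone_size_dist)
    probs = _clone_state_probs(rng, n_clones, states, state_probs)
    class_of_state = class_of_state or {s: s for s in states}

    # clone tags
    tags: list[tuple[int, ...] | frozenset[str]] = []
    if mode == "sticr":
        seen: set[tuple[int, ...]] = set()
        for _ in range(n_clones):
            for _ in range(10000):
                combo = tuple(int(rng.integers(0, ps)) for ps in pool_sizes)
                if combo not in seen:
                    seen.add(combo)
                    tags.append(combo)
                    break
            else:  # pragma: no cover - astronomically unlikely at 500^3
                raise ValueError("could not draw distinct barcodes for all clones")
    else:
        used: set[str] = set()
        for _ in range(n_clones):
            n_int = max(1, int(_draw_sizes(rng, 1, integrations_per_cell_dist)[0]))
            bcs: set[str] = set()
            while len(bcs) < n_int:
                bc = _tracker_barcode(rng, tracker_mask)
                if bc not in used:
                    used.add(bc)
                    bcs.add(bc)
            tags.append(frozenset(bcs))

    cells, clone_of, state_of, class_of, integ = [], {}, {}, {}, {}
    idx = 0
    for ci in range(n_clones):
        clone_id = f"clone{ci:05d}"
        for _ in range(int(sizes[ci])):
            cell = f"cell{idx:06d}"
            idx += 1
            cells.append(cell)
            clone_of[cell] = clone_id
            st = states[int(rng.choice(len(states), p=probs[ci]))]
            state_of[cell] = st
            class_of[cell] = class_of_state[st]
            integ[cell] = tags[ci]
    meta = {"mode": mode, "seed": seed}
    if mode == "trackerseq":
        meta["tracker_mask"] = tracker_mask
    else:
        meta["pool_sizes"] = tuple(pool_sizes)
    return SimulatedPopulation(
        cells=cells,
        clone_of=clone_of,
        state_of=state_of,
        class_of=class_of,
        integrations=integ,
        mode=mode,
        metadata=meta,
    )


def gen_coupled_population(
    n_clones: int = 100,
    n_coupled: int = 25,
    states: list[str] | None = None,
    coupled_pair: tuple[str, str] = ("s0", "s1"),
    clone_size_dist=("geometric", 0.2, 30),
    seed: int = 0,
    mode: str = "sticr",
    pool_sizes: tuple[int, ...] = (500, 500, 500),
) -> SimulatedPopulation:
    """Population with a planted lineage coupling between one state pair.

    ``n_coupled`` clones split their cells 50/50 between the two states of
    ``coupled_pair``; every other clone is coherent, homing all its cells on
    one state drawn uniformly from the remaining states. Per-state cell
    counts stay balanced, so the planted pair is the only state pair whose
    sharing exceeds the permutation null. With ``n_coupled=0`` all clones
    are single-state and no pair is coupled.
    """
    states = list(states) if states is not None else [f"s{i}" for i in range(8)]
    s1, s2 = coupled_pair
    if s1 not in states or s2 not in states or s1 == s2:
        raise ValueError("coupled_pair must name two distinct states")
    others = [s for s in states if s not in coupled_pair]
    if not others and n_coupled < n_clones:
        raise ValueError("no states left for uncoupled clones")
    rng = np.random.default_rng(seed)
    probs = []
    for i in range(n_clones):
        if i < n_coupled:
            probs.append({s: (0.5 if s in coupled_pair else 0.0) for s in states})
        else:
            home = others[int(rng.integers(0, len(others)))]
            probs.append({s: (1.0 if s == home else 0.0) for s in states})
    return gen_clonal_population(
        n_clones,
        clone_size_dist=clone_size_dist,
        states=states,
        state_probs=("per_clone", probs),
        mode=mode,
        seed=seed,
        pool_sizes=pool_sizes,
    )


def apply_integration_dropout(
    pop: SimulatedPopulation, rate: float, seed: int = 0, min_keep: int = 1
) -> SimulatedPopulation:
    """Per-cell random loss of integrations (TrackerSeq capture dropout).

    Each cell independently loses each of its clone's barcodes with
    probability ``rate``, keeping at least ``min_keep``; cells of a clone
    then carry overlapping-but-unequal subsets, the regime Jaccard clone
    calling must tolerate.
    """
    if pop.mode != "trackerseq":
        raise ValueError("dropout applies to TrackerSeq populations only")
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    integ: dict[str, frozenset[str]] = {}
    for cell in pop.cells:
        bcs = sorted(pop.integrations[cell])
        keep = [bc for bc in bcs if rng.random() >= rate]
        if len(keep) < min_keep:
            extra = [bc for bc in bcs if bc not in keep]
            rng.shuffle(extra)
            keep.extend(extra[: min_keep - len(keep)])
        integ[cell] = frozenset(keep)
    return SimulatedPopulation(
        cells=list(pop.cells),
        clone_of=dict(pop.clone_of),
        state_of=dict(pop.state_of),
        class_of=dict(pop.class_of),
        integrations=integ,
        mode=pop.mode,
        metadata={**pop.metadata, "dropout_rate": rate, "dropout_seed": seed},
    )


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Barcode read records: (cell_barcode, umi, payload, read_count)."""

    records: list[tuple[str, str, str, int]]
    mode: str
    cell_barcode_of: dict[str, str]  # cell id -> droplet cell barcode
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["cell_barcode", "umi", "payload", "read_count"]
        )


def _mutate(rng: np.random.Generator, seq: str, n_sub: int, lo: int = 0, hi: int | None = None) -> str:
    """Apply n_sub distinct substitutions within seq[lo:hi]."""
    hi = len(seq) if hi is None else hi
    pos = rng.choice(np.arange(lo, hi), size=n_sub, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def gen_reads(
    pop: SimulatedPopulation,
    library: BarcodeLibrary | None = None,
    umi_per_molecule_dist=("constant", 12),
    pcr_dup_dist=("constant", 1),
    umi_error_rate: float = 0.0,
    fragment_error_rate: float = 0.0,
    seed: int = 0,
    umi_length: int = DEFAULT_UMI_LENGTH,
    cell_barcode_length: int = DEFAULT_CELL_BARCODE_LENGTH,
) -> ReadSet:
    """Generate barcode reads for a population.

    STICR payloads are ``frag1+frag2+frag3+viral_index`` at fixed offsets,
    realized from ``library``; TrackerSeq payloads are the 37-nt integration
    barcodes themselves (``library`` must be None). Per (cell, barcode) a
    number of distinct UMIs is drawn, each backed by ``pcr_dup_dist`` PCR
    duplicate reads. With probability ``umi_error_rate`` a UMI also emits a
    single-substitution error copy (1 read); with probability
    ``fragment_error_rate`` a record's payload acquires 1-2 substitutions
    confined to one fragment.
    """
    if not 0 <= umi_error_rate <= 1 or not 0 <= fragment_error_rate <= 1:
        raise ValueError("error rates must lie in [0, 1]")
    if pop.mode == "sticr":
        if library is None:
            raise ValueError("STICR read generation requires a fragment library")
        if library.pool_sizes != tuple(pop.metadata.get("pool_sizes", library.pool_sizes)):
            raise ValueError("population pool sizes do not match the library")
    elif library is not None:
        raise ValueError("TrackerSeq populations take no fragment library")

    rng = np.random.default_rng(seed)
    cbs = _distinct_random_strings(rng, len(pop.cells), cell_barcode_length)
    cell_barcode_of = dict(zip(pop.cells, cbs))

    frag_len = library.fragment_length if library else None
    records: list[tuple[str, str, str, int]] = []
    for cell in pop.cells:
        cb = cell_barcode_of[cell]
        tag = pop.integrations[cell]
        if pop.mode == "sticr":
            payloads = [library.combination_sequence(tag)]  # type: ignore[arg-type]
        else:
            payloads = sorted(tag)  # type: ignore[arg-type]
        for payload in payloads:
            n_umi = max(1, int(_draw_sizes(rng, 1, umi_per_molecule_dist)[0]))
            umis = _distinct_random_strings(rng, n_umi, umi_length)
            for umi in umis:
                n_reads = max(1, int(_draw_sizes(rng, 1, pcr_dup_dist)[0]))
                pl = payload
                if fragment_error_rate and rng.random() < fragment_error_rate:
                    fi = int(rng.integers(0, 3)) if pop.mode == "sticr" else 0
                    lo = fi * frag_len if frag_len else 0
                    hi = lo + frag_len if frag_len else len(pl)
                    pl = _mutate(rng, pl, int(rng.integers(1, 3)), lo, hi)
                records.append((cb, umi, pl, n_reads))
                if umi_error_rate and rng.random() < umi_error_rate:
                    records.append((cb, _mutate(rng, umi, 1), pl, 1))
    meta = {
        "mode": pop.mode,
        "seed": seed,
        "umi_length": umi_length,
        "cell_barcode_length": cell_barcode_length,
    }
    meta.update({k: v for k, v in pop.metadata.items() if k == "tracker_mask"})
    return ReadSet(
        records=records, mode=pop.mode, cell_barcode_of=cell_barcode_of, metadata=meta
    )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def gen_expression_pair(
    cluster_map: dict[str, str],
    n_genes: int = 200,
    n_marker_per_cluster: int = 10,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    cells_per_cluster: int = 100,
    seed: int = 0,
    baseline: float = 0.5,
):
    """Matched embryonic/postnatal expression matrices with shared markers.

    Each embryonic cluster and its mapped postnatal cluster share a disjoint
    block of ``n_marker_per_cluster`` marker genes whose mean is elevated by
    ``effect`` over a ``baseline``; Gaussian noise of ``noise_sd`` is added
    and values clipped at zero, emulating log-normalized expression in which
    matched cell types keep their marker signature across development.

    Returns ``(emb_expr, emb_labels, post_expr, post_labels, genes)`` with
    expression as cells x genes DataFrames.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    emb_clusters = list(cluster_map)
    post_clusters = list(dict.fromkeys(cluster_map.values()))
    if len(post_clusters) != len(emb_clusters):
        raise ValueError("cluster_map must be one-to-one")
    n_cl = len(emb_clusters)
    if n_genes < n_cl * n_marker_per_cluster:
        raise ValueError("n_genes smaller than the total number of marker genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    marker_idx = {
        cl: np.arange(i * n_marker_per_cluster, (i + 1) * n_marker_per_cluster)
        for i, cl in enumerate(emb_clusters)
    }

    def _matrix(clusters, marker_of, prefix):
        rows, labels, names = [], [], []
        for cl in clusters:
            mean = np.full(n_genes, baseline)
            mean[marker_of[cl]] += effect
            x = mean + rng.normal(0.0, noise_sd, size=(cells_per_cluster, n_genes))
            rows.append(np.clip(x, 0.0, None))
            labels.extend([cl] * cells_per_cluster)
            names.extend(
                f"{prefix}_{cl}_{i:04d}" for i in range(cells_per_cluster)
            )
        expr = pd.DataFrame(np.vstack(rows), index=names, columns=genes)
        return expr, pd.Series(labels, index=names, name="cluster")

    emb_expr, emb_labels = _matrix(emb_clusters, marker_idx, "emb")
    post_marker = {cluster_map[e]: marker_idx[e] for e in emb_clusters}
    post_expr, post_labels = _matrix(post_clusters, post_marker, "post")
    return emb_expr, emb_labels, post_expr, post_labels, genes
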