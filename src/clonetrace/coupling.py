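"""Lineage coupling statistics over a clone table and cell-state annotation.

For a state pair {s1, s2} and a clone of n cells with k cells in s1 or s2,
the clone is *shared* when k >= 2 with at least one cell in each state, and
contributes p = k/n. The pair metric is the sum of p over shared clones.
Its null distribution comes from shuffling state labels over cells while
preserving per-state counts (one global shuffle per iteration serves all
pairs); the coupling z-score is (observed - null mean) / null sd, positive
when two states share more clones than chance. The coupling correlation
between two states is the Pearson correlation of their z-score vectors
against all other states, and average-linkage clustering of Euclidean
distances between correlation rows yields the lineage dendrogram.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .sticr import CloneTable

GLIA_CLASSES = frozenset({"astrocyte", "opc", "oligodendrocyte"})
NEURON_CLASSES = frozenset({"neuron"})


@dataclass
class StateAnnotation:
    """Per-cell state (cluster) and optional class labels."""

    state_of: dict[str, str]
    class_of: dict[str, str] | None = None
    states: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.states:
            self.states = sorted(set(self.state_of.values()))
        if not self.states:
            raise ValueError("state set must be non-empty")
        unknown = set(self.state_of.values()) - set(self.states)
        if unknown:
            raise ValueError(f"cells annotated with undeclared states: {sorted(unknown)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StateAnnotation":
        class_of = (
            dict(zip(df["cell"], df["class"])) if "class" in df.columns else None
        )
        return cls(state_of=dict(zip(df["cell"], df["state"])), class_of=class_of)


@dataclass
class CouplingResult:
    """Observed metric, permutation null moments, z-scores and correlations."""

    states: list[str]
    observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    z: pd.DataFrame
    corr: pd.DataFrame | None
    sd_zero: pd.DataFrame
    n_perm: int
    seed: int


def _index_instance(table: CloneTable, ann: StateAnnotation):
    """Clone/state integer encoding of every cell in the table."""
    cells = table.cells
    missing = [c for c in cells if c not in ann.state_of]
    if missing:
        raise ValueError(f"cells without a state annotation: {missing[:3]}")
    clone_ids = sorted(table.clones)
    clone_idx = {cid: i for i, cid in enumerate(clone_ids)}
    state_idx = {s: i for i, s in enumerate(ann.states)}
    clone_of = table.clone_of()
    ci = np.array([clone_idx[clone_of[c]] for c in cells])
    si = np.array([state_idx[ann.state_of[c]] for c in cells])
    sizes = np.bincount(ci, minlength=len(clone_ids)).astype(float)
    return ci, si, sizes, len(clone_ids), len(ann.states)


def _metric_pairs(ci, si, sizes, n_clones, n_states, pi, pj):
    """Vectorized pair metric for index arrays pi, pj of state pairs."""
    C = np.bincount(ci * n_states + si, minlength=n_clones * n_states).reshape(
        n_clones, n_states
    )
    A = C[:, pi]
    B = C[:, pj]
    K = A + B
    shared = (K >= 2) & (A >= 1) & (B >= 1)
    return ((K / sizes[:, None]) * shared).sum(axis=0)


def pair_metric(table: CloneTable, ann: StateAnnotation, s1: str, s2: str) -> float:
    """Shared-clone metric for one state pair: sum over shared clones of k/n."""
    if s1 == s2:
        raise ValueError("the metric is defined for pairs of two distinct states")
    for s in (s1, s2):
        if s not in ann.states:
            raise ValueError(f"unknown state label: {s!r}")
    ci, si, sizes, n_clones, n_states = _index_instance(table, ann)
    idx = {s: i for i, s in enumerate(ann.states)}
    return float(
        _metric_pairs(ci, si, sizes, n_clones, n_states, np.array([idx[s1]]), np.array([idx[s2]]))[0]
    )


def coupling_zscores(
    table: CloneTable,
    ann: StateAnnotation,
    n_perm: int = 10000,
    seed: int = 0,
    compute_correlations: bool = True,
) -> CouplingResult:
    """Permutation z-scores of the shared-clone metric for all state pairs.

    Each of the ``n_perm`` iterations shuffles the state assignments of the
    individual cells (exactly preserving per-state cell counts, since a
    shuffle is a permutation of the observed label vector) and recomputes
    the metric for every pair. The null sd is the population standard
    deviation over iterations; pairs with sd = 0 get z = 0 and are flagged.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if len(ann.states) < 2:
        raise ValueError("need at least 2 states")
    ci, si, sizes, n_clones, n_states = _index_instance(table, ann)
    if len(ci) < n_states:
        raise ValueError("fewer cells than states")
    pi, pj = np.triu_indices(n_states, k=1)
    obs = _metric_pairs(ci, si, sizes, n_clones, n_states, pi, pj)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(pi)))
    for it in range(n_perm):
        null[it] = _metric_pairs(
            ci, rng.permutation(si), sizes, n_clones, n_states, pi, pj
        )
    mu = null.mean(axis=0)
    sd = null.std(axis=0)  # population sd; n vs n-1 immaterial at large N
    zero = sd == 0
    z = np.zeros_like(obs)
    z[~zero] = (obs[~zero] - mu[~zero]) / sd[~zero]

    def _sym(vec, diag=np.nan):
        m = np.full((n_states, n_states), diag)
        m[pi, pj] = vec
        m[pj, pi] = vec
        return pd.DataFrame(m, index=ann.states, columns=ann.states)

    result = CouplingResult(
        states=list(ann.states),
        observed=_sym(obs),
        null_mean=_sym(mu),
        null_sd=_sym(sd),
        z=_sym(z),
        corr=None,
        sd_zero=_sym(zero.astype(float), diag=0).astype(bool),
        n_perm=n_perm,
        seed=seed,
    )
    if compute_correlations:
        result.corr = coupling_correlations(result)
    return result


def coupling_correlations(result: CouplingResult) -> pd.DataFrame:
    """Pearson correlation between the z-score vectors of each state pair.

    For pair (s1, s2) the compared vectors are z(s1, .) and z(s2, .) with
    the diagonal and the s1/s2 entries themselves excluded, avoiding
    self-inflation. A constant vector makes the correlation undefined; such
    pairs are reported as 0.
    """
    states = result.states
    S = len(states)
    zm = result.z.to_numpy()
    out = np.eye(S)
    for a in range(S):
        for b in range(a + 1, S):
            keep = np.ones(S, dtype=bool)
            keep[[a, b]] = False
            x, y = zm[a, keep], zm[b, keep]
            if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            out[a, b] = out[b, a] = r
    return pd.DataFrame(out, index=states, columns=states)


def lineage_dendrogram(
    corr: pd.DataFrame, n_groups: int | None = None, height: float | None = None
):
    """Average-linkage tree over Euclidean distances between correlation rows.

    Returns ``(Z, groups)`` where ``Z`` is the scipy linkage matrix and
    ``groups`` maps each state to its flat clonal group (by requested group
    count or cut height; None for both returns leaves ungrouped as one).
    """
    if len(corr) < 2:
        raise ValueError("need at least 2 states for a dendrogram")
    Z = linkage(pdist(corr.to_numpy(), metric="euclidean"), method="average")
    if n_groups is not None:
        labels = fcluster(Z, t=n_groups, criterion="maxclust")
    elif height is not None:
        labels = fcluster(Z, t=height, criterion="distance")
    else:
        labels = np.ones(len(corr), dtype=int)
    groups = pd.Series(labels, index=corr.index, name="clonal_group")
    return Z, groups


def clone_composition(
    table: CloneTable,
    ann: StateAnnotation,
    glia_classes: frozenset[str] = GLIA_CLASSES,
    neuron_classes: frozenset[str] = NEURON_CLASSES,
):
    """Per-clone dominant-class fraction, purity category and lineage category.

    Purity categories: "100%" (every cell one class), ">80%" (0.8 < fraction
    < 1) and "<80%" (fraction <= 0.8). Lineage categories partition clones
    into glia_only / neuron_only / mixed by the glia and neuron classes
    present; clones containing neither glia nor neurons are set aside as
    "other" and excluded from those fractions.
    """
    if ann.class_of is None:
        raise ValueError("clone composition requires class annotations")
    rows = []
    for cid in sorted(table.clones):
        cells = table.clones[cid]
        classes = []
        for c in sorted(cells):
            if c not in ann.class_of:
                raise ValueError(f"cell without class annotation: {c}")
            classes.append(ann.class_of[c])
        counts = Counter(classes)
        frac = max(counts.values()) / len(classes)
        if frac == 1.0:
            category = "100%"
        elif frac > 0.8:
            category = ">80%"
        else:
            category = "<80%"
        present = set(counts)
        has_glia = bool(present & glia_classes)
        has_neuron = bool(present & neuron_classes)
        if has_glia and has_neuron:
            lineage = "mixed"
        elif has_glia:
            lineage = "glia_only"
        elif has_neuron:
            lineage = "neuron_only"
        else:
            lineage = "other"
        rows.append(
            (cid, table.dataset_of[cid], len(classes), frac, category, lineage)
        )
    per_clone = pd.DataFrame(
        rows,
        columns=["clone", "dataset", "n_cells", "dominant_fraction", "category", "lineage"],
    )
    summaries = []
    for ds, grp in per_clone.groupby("dataset", sort=True):
        cat = grp["category"].value_counts(normalize=True)
        lin = grp.loc[grp["lineage"] != "other", "lineage"].value_counts(normalize=True)
        summaries.append(
            {
                "dataset": ds,
                "n_clones": len(grp),
                "n_other": int((grp["lineage"] == "other").sum()),
                **{f"frac_{k}": float(cat.get(k, 0.0)) for k in ("100%", ">80%", "<80%")},
                **{
                    f"frac_{k}": float(lin.get(k, 0.0))
                    for k in ("glia_only", "neuron_only", "mixed")
                },
            }
        )
    return per_clone, pd.DataFrame(summaries)


def clone_intersections(
    table: CloneTable,
    ann: StateAnnotation,
    selected_states: list[str],
    dispersing_only: bool = False,
):
    """Clone counts per distinct set of occupied selected states (UpSet input).

    Each clone maps to the subset of ``selected_states`` it occupies; clones
    occupying none are ignored, and with ``dispersing_only`` clones
    occupying fewer than 2 selected states are dropped. Also returns the
    per-state cell counts used as UpSet set sizes.
    """
    if not selected_states:
        raise ValueError("empty state selection")
    unknown = set(selected_states) - set(ann.states)
    if unknown:
        raise ValueError(f"unknown states selected: {sorted(unknown)}")
    sel = list(dict.fromkeys(selected_states))
    counts: Counter = Counter()
    for cid in sorted(table.clones):
        occupied = frozenset(
            s
            for s in sel
            if any(ann.state_of[c] == s for c in table.clones[cid])
        )
        if not occupied:
            continue
        if dispersing_only and len(occupied) < 2:
            continue
        counts[occupied] += 1
    inter = pd.DataFrame(
        [
            {"states": "&".join(sorted(k, key=sel.index)), "n_clones": v}
            for k, v in sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
        ]
    )
    state_of = ann.state_of
    set_sizes = pd.Series(
        {s: sum(1 for c in table.cells if state_of[c] == s) for s in sel},
        name="n_cells",
    )
    return inter, set_sizes
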