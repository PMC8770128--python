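"""Correlation-based mapping of embryonic cells onto postnatal cell types.

Each postnatal cluster is summarized by a *model vector*: the average
log-normalized expression of its cells over a shared variable-gene list.
Every embryonic cell is assigned to the cluster whose model vector it
correlates with best (Pearson). Significance comes from permuting each
cell's expression values across genes (models unchanged, 100 permutations
by default), recording the largest permuted correlation per cell, and
counting the fraction strictly larger than the observed best correlation;
the empirical p-values are Benjamini-Hochberg adjusted and only cells with
FDR below 0.1 are mapped. Cluster-level structure is compared with a
Spearman correlation distance between average expression vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests


@dataclass
class ModelVectors:
    clusters: list[str]
    genes: list[str]
    vectors: pd.DataFrame  # clusters x genes

    def __post_init__(self):
        if not np.isfinite(self.vectors.to_numpy()).all():
            raise ValueError("model vectors must be finite")


def build_model_vectors(
    expr: pd.DataFrame, labels: pd.Series, genes: list[str]
) -> ModelVectors:
    """Average log-normalized expression per cluster over ``genes``.

    ``expr`` is cells x genes; ``labels`` assigns each cell a cluster.
    """
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing[:3]}")
    labels = labels.reindex(expr.index)
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    sub = expr[list(genes)]
    vectors = sub.groupby(labels, sort=True).mean()
    empty = set(labels.unique()) - set(vectors.index)
    if empty:
        raise ValueError(f"empty clusters: {sorted(empty)}")
    return ModelVectors(
        clusters=list(vectors.index), genes=list(genes), vectors=vectors
    )


def _standardize_rows(x: np.ndarray):
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    xs = np.zeros_like(x, dtype=float)
    xs[ok] = (x[ok] - mu[ok]) / sd[ok]
    return xs, ok


def _pearson_to_models(cells_std: np.ndarray, models_std: np.ndarray) -> np.ndarray:
    return cells_std @ models_std.T / cells_std.shape[1]


def map_cells(expr: pd.DataFrame, models: ModelVectors) -> pd.DataFrame:
    """Best-correlated postnatal cluster per embryonic cell.

    Returns a per-cell frame with best_cluster, best_r, a tie flag
    (broken by declared cluster order) and a zero-variance flag (such cells
    cannot be correlated and stay unassigned); the full correlation matrix
    is attached as ``result.attrs["r"]``.
    """
    if list(expr.columns) != list(models.genes):
        missing = set(models.genes) - set(expr.columns)
        if missing:
            raise ValueError(f"cell matrix lacks model genes: {sorted(missing)[:3]}")
        expr = expr[list(models.genes)]
    x, x_ok = _standardize_rows(expr.to_numpy(dtype=float))
    m, m_ok = _standardize_rows(models.vectors.to_numpy(dtype=float))
    if not m_ok.all():
        raise ValueError("constant model vector")
    r = _pearson_to_models(x, m)
    best = r.argmax(axis=1)
    best_r = r[np.arange(len(r)), best]
    ties = (r == best_r[:, None]).sum(axis=1) > 1
    out = pd.DataFrame(
        {
            "best_cluster": [models.clusters[j] for j in best],
            "best_r": best_r,
            "tie": ties,
            "zero_variance": ~x_ok,
        },
        index=expr.index,
    )
    out.loc[~x_ok, "best_cluster"] = None
    out.loc[~x_ok, "best_r"] = np.nan
    out.attrs["r"] = pd.DataFrame(r, index=expr.index, columns=models.clusters)
    return out


def empirical_pvalues(
    expr: pd.DataFrame,
    models: ModelVectors,
    assignments: pd.DataFrame | None = None,
    n_perm: int = 100,
    seed: int = 0,
    scheme: str = "within_cell",
) -> pd.Series:
    """Permutation p-value for each cell's cluster assignment.

    Per permutation each cell's expression values are shuffled across genes
    (``scheme="within_cell"``, the default: the models stay fixed and each
    cell keeps its value distribution) or each gene's values across cells
    (``"within_gene"``). The per-cell maximum correlation to any model is
    tracked, and p = fraction of the ``n_perm`` maxima strictly larger than
    the observed best correlation (zero p-values are possible).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in ("within_cell", "within_gene"):
        raise ValueError(f"unknown permutation scheme: {scheme!r}")
    if assignments is None:
        assignments = map_cells(expr, models)
    expr = expr[list(models.genes)]
    x = expr.to_numpy(dtype=float)
    xs, x_ok = _standardize_rows(x)
    m, _ = _standardize_rows(models.vectors.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    best_r = assignments["best_r"].to_numpy()
    exceed = np.zeros(len(x), dtype=np.int64)
    for _ in range(n_perm):
        if scheme == "within_cell":
            # permuting a standardized row is the standardized permuted row
            perm = rng.permuted(xs, axis=1)
        else:
            perm = rng.permuted(xs, axis=0)
        max_r = _pearson_to_models(perm, m).max(axis=1)
        exceed += max_r > best_r
    p = exceed / n_perm
    p[~x_ok] = np.nan
    return pd.Series(p, index=expr.index, name="p_emp")


def fdr_gate(p_emp: pd.Series, threshold: float = 0.1) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment; a cell is mapped iff FDR < threshold."""
    p = p_emp.to_numpy(dtype=float)
    if np.nanmin(p, initial=0) < 0 or np.nanmax(p, initial=0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    ok = ~np.isnan(p)
    fdr = np.full_like(p, np.nan)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    mapped = np.zeros(len(p), dtype=bool)
    mapped[ok] = fdr[ok] < threshold
    return pd.DataFrame({"p_emp": p, "fdr": fdr, "mapped": mapped}, index=p_emp.index)


def map_embryonic_cells(
    emb_expr: pd.DataFrame,
    post_expr: pd.DataFrame,
    post_labels: pd.Series,
    genes: list[str],
    n_perm: int = 100,
    fdr_threshold: float = 0.1,
    seed: int = 0,
    scheme: str = "within_cell",
) -> pd.DataFrame:
    """End-to-end mapping: model vectors, assignment, permutation p, FDR gate."""
    models = build_model_vectors(post_expr, post_labels, genes)
    assignments = map_cells(emb_expr[list(genes)], models)
    p = empirical_pvalues(
        emb_expr[list(genes)], models, assignments, n_perm=n_perm, seed=seed, scheme=scheme
    )
    gate = fdr_gate(p, threshold=fdr_threshold)
    out = assignments.join(gate)
    out.attrs["params"] = {
        "n_perm": n_perm,
        "fdr_threshold": fdr_threshold,
        "seed": seed,
        "permutation_scheme": scheme,
    }
    return out


def mapping_fractions(result: pd.DataFrame, emb_labels: pd.Series) -> pd.DataFrame:
    """Per embryonic cluster, the fraction of its *mapped* cells assigned to
    each postnatal cluster (rows sum to 1; all-NaN rows mark clusters with
    zero mapped cells)."""
    emb_labels = emb_labels.reindex(result.index)
    mapped = result[result["mapped"]]
    targets = sorted(result["best_cluster"].dropna().unique())
    rows = {}
    for cl in sorted(emb_labels.dropna().unique()):
        sub = mapped[emb_labels.loc[mapped.index] == cl]
        if len(sub) == 0:
            rows[cl] = {t: np.nan for t in targets}
        else:
            frac = sub["best_cluster"].value_counts(normalize=True)
            rows[cl] = {t: float(frac.get(t, 0.0)) for t in targets}
    return pd.DataFrame.from_dict(rows, orient="index")[targets]


def cluster_distance_spearman(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """1 - Spearman rho between average cluster expression vectors.

    ``expr`` is cells x genes with log-normalized values. Pairs involving a
    constant average vector are undefined and reported NaN.
    """
    labels = labels.reindex(expr.index)
    means = expr.groupby(labels, sort=True).mean()
    if len(means) < 2:
        raise ValueError("need at least 2 clusters")
    x = means.to_numpy(dtype=float)
    rho = spearmanr(x, axis=1)[0]
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two variables
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    const = x.std(axis=1) == 0
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist[const, :] = np.nan
    dist[:, const] = np.nan
    return pd.DataFrame(dist, index=means.index, columns=means.index)
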