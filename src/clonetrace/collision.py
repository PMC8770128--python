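"""Monte-Carlo model of lineage-barcode collisions.

When a population of n progenitors is labelled from a library of D barcodes
with abundances p_i, two progenitors can draw the same barcode (a
collision), which would fuse unrelated clones downstream. Each replicate
draws n barcodes independently with replacement and records the number of
unique barcodes; collisions = n - unique. The closed-form expectation
E[unique] = sum_i (1 - (1 - p_i)^n) serves as an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_POPULATION_SIZES = tuple(int(10**k) for k in range(1, 7))

#: draws-per-population-size budget; replicate counts are reduced (never
#: below 200) so n * n_reps_used stays within it, with the SE reported.
DEFAULT_DRAW_BUDGET = 20_000_000


@dataclass(frozen=True)
class CollisionConfig:
    library_size: int
    abundances: np.ndarray | None = None  # None = uniform over library_size
    population_sizes: tuple[int, ...] = DEFAULT_POPULATION_SIZES
    n_reps: int = 20000
    seed: int = 0
    draw_budget: int = DEFAULT_DRAW_BUDGET

    def __post_init__(self):
        if self.library_size < 1:
            raise ValueError("library size must be >= 1")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.abundances is not None:
            p = np.asarray(self.abundances, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("abundances must be non-negative and sum to 1")
            if len(p) != self.library_size:
                raise ValueError("abundances length must equal library size")
            object.__setattr__(self, "abundances", p)


def expected_unique(abundances: np.ndarray | int, n: int) -> float:
    """Exact E[number of unique barcodes] after n independent draws.

    ``abundances`` is a probability vector, or an int D for a uniform
    library of size D.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if isinstance(abundances, (int, np.integer)):
        D = int(abundances)
        return float(D * (1.0 - (1.0 - 1.0 / D) ** n))
    p = np.asarray(abundances, dtype=float)
    return float(np.sum(1.0 - (1.0 - p) ** n))


def _unique_counts_uniform(rng, D, n, reps) -> np.ndarray:
    out = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        out[r] = len(np.unique(rng.integers(0, D, size=n)))
    return out


def _unique_counts_weighted(rng, p, n, reps) -> np.ndarray:
    D = len(p)
    # multinomial occupancy: exact categorical sampling semantics
    if D * min(reps, 256) <= 50_000_000:
        out = np.empty(reps, dtype=np.int64)
        done = 0
        chunk = max(1, 50_000_000 // max(D, 1))
        while done < reps:
            k = min(chunk, reps - done)
            counts = rng.multinomial(n, p, size=k)
            out[done : done + k] = (counts > 0).sum(axis=1)
            done += k
        return out
    out = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        out[r] = len(np.unique(rng.choice(D, size=n, p=p)))
    return out


def simulate_collisions(config: CollisionConfig) -> pd.DataFrame:
    """Monte-Carlo collision curve over the configured population sizes.

    Returns a DataFrame with columns n, mean_unique, mean_collisions, se,
    n_reps_used, scaled_down. ``scaled_down`` marks population sizes where
    the replicate count was reduced to honour the draw budget; the standard
    error reflects the replicates actually run.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for n in config.population_sizes:
        reps = config.n_reps
        scaled = False
        if n * reps > config.draw_budget:
            reps = max(200, config.draw_budget // max(n, 1))
            scaled = True
        if config.abundances is None:
            uniq = _unique_counts_uniform(rng, config.library_size, n, reps)
        else:
            uniq = _unique_counts_weighted(rng, config.abundances, n, reps)
        mean_u = float(uniq.mean())
        se = float(uniq.std(ddof=1) / np.sqrt(reps)) if reps > 1 else float("nan")
        rows.append(
            {
                "n": int(n),
                "mean_unique": mean_u,
                "mean_collisions": float(n - mean_u),
                "se": se,
                "n_reps_used": int(reps),
                "scaled_down": scaled,
            }
        )
    return pd.DataFrame(rows)
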