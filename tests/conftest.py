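import numpy as np
import pytest

import clonetrace as ct


@pytest.fixture(scope="session")
def small_library():
    return ct.gen_barcode_library([20, 20, 20], seed=11)


@pytest.fixture(scope="session")
def sticr_population(small_library):
    return ct.gen_clonal_population(
        40,
        clone_size_dist=("geometric", 0.35, 30),
        states=["a", "b", "c"],
        seed=21,
        pool_sizes=small_library.pool_sizes,
    )


@pytest.fixture(scope="session")
def tracker_population():
    return ct.gen_clonal_population(
        30,
        clone_size_dist=("constant", 4),
        states=["a", "b"],
        mode="trackerseq",
        integrations_per_cell_dist=("constant", 8),
        seed=31,
    )


def truth_table(pop):
    return ct.CloneTable.from_clone_map(pop.clone_of)


def recovery_ari(pop, readset, table):
    """ARI between ground-truth clones and a called clone table."""
    from sklearn.metrics import adjusted_rand_score

    cb2cell = {v: k for k, v in readset.cell_barcode_of.items()}
    called = table.clone_of()
    cells = sorted(called)
    truth = [pop.clone_of[cb2cell[c]] for c in cells]
    pred = [called[c] for c in cells]
    return adjusted_rand_score(truth, pred), len(cells)


@pytest.fixture(scope="session")
def expression_pair():
    return ct.gen_expression_pair(
        {f"E{i}": f"P{i}" for i in range(5)}, seed=41
    )
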