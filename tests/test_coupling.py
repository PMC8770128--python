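"""The shared-clone pair metric, its permutation z-scores (checked against
exhaustive enumeration on tiny instances), coupling correlations, the
lineage dendrogram, clone composition and intersection counts."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

import clonetrace as ct
from clonetrace.coupling import StateAnnotation


def make_instance(assignments):
    """assignments: dict cell -> (clone, state[, class])."""
    clone_of = {c: v[0] for c, v in assignments.items()}
    state_of = {c: v[1] for c, v in assignments.items()}
    class_of = {c: v[2] for c, v in assignments.items() if len(v) > 2}
    table = ct.CloneTable.from_clone_map(clone_of)
    ann = StateAnnotation(state_of=state_of, class_of=class_of or None)
    return table, ann


def enumerate_metric(clone_of, state_of, s1, s2):
    """Direct transcription of the shared-clone definitions: per clone,
    k = cells in s1 or s2; shared iff k >= 2 with both states hit; sum k/n."""
    total = 0.0
    for clone in set(clone_of.values()):
        cells = [c for c in clone_of if clone_of[c] == clone]
        k = sum(1 for c in cells if state_of[c] in (s1, s2))
        in1 = any(state_of[c] == s1 for c in cells)
        in2 = any(state_of[c] == s2 for c in cells)
        if k >= 2 and in1 and in2:
            total += k / len(cells)
    return total


class TestPairMetric:
    def test_hand_instance(self):
        # clone A: {2 in s1, 1 in s2} -> k=n=3, p=1
        # clone B: {1 s1, 1 s2, 2 s3} -> k=2, n=4, p=0.5
        table, ann = make_instance({
            "a1": ("A", "s1"), "a2": ("A", "s1"), "a3": ("A", "s2"),
            "b1": ("B", "s1"), "b2": ("B", "s2"), "b3": ("B", "s3"), "b4": ("B", "s3"),
        })
        assert ct.pair_metric(table, ann, "s1", "s2") == pytest.approx(1.5)

    def test_two_cell_clone(self):
        table, ann = make_instance({"x": ("A", "s1"), "y": ("A", "s2")})
        assert ct.pair_metric(table, ann, "s1", "s2") == 1.0

    def test_no_shared_clone_is_zero(self):
        table, ann = make_instance({"x": ("A", "s1"), "y": ("B", "s2")})
        assert ct.pair_metric(table, ann, "s1", "s2") == 0.0

    def test_symmetry_and_errors(self):
        table, ann = make_instance({
            "a": ("A", "s1"), "b": ("A", "s2"), "c": ("B", "s2"), "d": ("B", "s1"),
        })
        assert ct.pair_metric(table, ann, "s1", "s2") == ct.pair_metric(table, ann, "s2", "s1")
        with pytest.raises(ValueError):
            ct.pair_metric(table, ann, "s1", "s1")
        with pytest.raises(ValueError):
            ct.pair_metric(table, ann, "s1", "zz")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        states = [f"s{i}" for i in range(4)]
        clone_of, state_of = {}, {}
        for ci in range(int(rng.integers(2, 10))):
            for j in range(int(rng.integers(1, 6))):
                cell = f"c{ci}_{j}"
                clone_of[cell] = f"k{ci}"
                state_of[cell] = states[rng.integers(0, 4)]
        table = ct.CloneTable.from_clone_map(clone_of)
        ann = StateAnnotation(state_of=state_of, states=states)
        for s1, s2 in itertools.combinations(states, 2):
            assert ct.pair_metric(table, ann, s1, s2) == pytest.approx(
                enumerate_metric(clone_of, state_of, s1, s2)
            )


class TestZScores:
    def test_all_singletons_flagged_zero(self):
        table, ann = make_instance({
            "a": ("A", "s1"), "b": ("B", "s2"), "c": ("C", "s1"), "d": ("D", "s2"),
        })
        res = ct.coupling_zscores(table, ann, n_perm=50, seed=1)
        assert res.observed.loc["s1", "s2"] == 0
        assert res.z.loc["s1", "s2"] == 0
        assert bool(res.sd_zero.loc["s1", "s2"])

    def test_monte_carlo_matches_exhaustive(self):
        # 7 cells: every permutation of the label multiset enumerated exactly
        table, ann = make_instance({
            "a1": ("A", "s1"), "a2": ("A", "s1"), "a3": ("A", "s2"),
            "b1": ("B", "s2"), "b2": ("B", "s3"),
            "c1": ("C", "s1"), "c2": ("C", "s3"),
        })
        clone_of = table.clone_of()
        cells = sorted(clone_of)
        labels = [ann.state_of[c] for c in cells]
        states = ann.states
        pairs = list(itertools.combinations(states, 2))
        null: dict = {p: [] for p in pairs}
        for perm in itertools.permutations(labels):
            so = dict(zip(cells, perm))
            for p in pairs:
                null[p].append(enumerate_metric(clone_of, so, *p))
        res = ct.coupling_zscores(table, ann, n_perm=10000, seed=3)
        for s1, s2 in pairs:
            arr = np.array(null[(s1, s2)])
            mu, sd = arr.mean(), arr.std()
            obs = enumerate_metric(clone_of, dict(zip(cells, labels)), s1, s2)
            z_exact = (obs - mu) / sd
            z_mc = res.z.loc[s1, s2]
            se_z = np.sqrt((1 + z_exact**2 / 2) / res.n_perm)
            assert abs(z_mc - z_exact) <= 3 * se_z
            assert res.null_mean.loc[s1, s2] == pytest.approx(mu, abs=4 * sd / np.sqrt(res.n_perm))

    def test_seed_reproducibility(self):
        pop = ct.gen_coupled_population(n_clones=20, n_coupled=5, seed=4)
        table = ct.CloneTable.from_clone_map(pop.clone_of)
        ann = StateAnnotation(state_of=pop.state_of)
        a = ct.coupling_zscores(table, ann, n_perm=200, seed=9)
        b = ct.coupling_zscores(table, ann, n_perm=200, seed=9)
        assert a.z.equals(b.z) and a.corr.equals(b.corr)

    def test_degenerate_inputs_fail(self):
        table, ann = make_instance({"a": ("A", "s1"), "b": ("A", "s2")})
        with pytest.raises(ValueError):
            ct.coupling_zscores(table, ann, n_perm=1)
        single = StateAnnotation(state_of={"a": "s1", "b": "s1"})
        with pytest.raises(ValueError):
            ct.coupling_zscores(table, single, n_perm=10)


class TestCorrelations:
    def _result_with_z(self, z):
        states = [f"s{i}" for i in range(len(z))]
        df = pd.DataFrame(z, index=states, columns=states)
        return ct.CouplingResult(
            states=states, observed=df, null_mean=df, null_sd=df, z=df,
            corr=None, sd_zero=df == np.inf, n_perm=0, seed=0,
        )

    def test_identical_rows_correlate_to_one(self):
        z = np.array([
            [np.nan, 0.0, 1.0, 2.0],
            [0.0, np.nan, 1.0, 2.0],
            [1.0, 1.0, np.nan, 0.5],
            [2.0, 2.0, 0.5, np.nan],
        ])
        corr = ct.coupling_correlations(self._result_with_z(z))
        # rows s0 and s1 agree on the compared entries (s2, s3)
        assert corr.loc["s0", "s1"] == pytest.approx(1.0)

    def test_sign_flip_correlates_to_minus_one(self):
        z = np.array([
            [np.nan, 0.0, 1.0, 2.0],
            [0.0, np.nan, -1.0, -2.0],
            [1.0, -1.0, np.nan, 0.5],
            [2.0, -2.0, 0.5, np.nan],
        ])
        corr = ct.coupling_correlations(self._result_with_z(z))
        assert corr.loc["s0", "s1"] == pytest.approx(-1.0)

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(5, 5))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        corr = ct.coupling_correlations(self._result_with_z(z))
        keep = [2, 3, 4]
        x, y = z[0, keep], z[1, keep]
        expected = np.corrcoef(x, y)[0, 1]
        assert corr.loc["s0", "s1"] == pytest.approx(expected)

    def test_constant_vector_flagged_zero(self):
        z = np.full((4, 4), 1.0)
        np.fill_diagonal(z, np.nan)
        corr = ct.coupling_correlations(self._result_with_z(z))
        assert corr.loc["s0", "s1"] == 0.0


class TestDendrogram:
    def test_identical_rows_merge_first(self):
        corr = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [0, 0, 1.0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        Z, groups = ct.lineage_dendrogram(corr, n_groups=2)
        assert Z[0, 2] == 0.0  # first merge at height zero
        assert groups["a"] == groups["b"] != groups["c"]

    def test_block_structure_recovered(self):
        block = np.kron(np.eye(2), np.ones((2, 2)))
        corr = pd.DataFrame(block, index=list("abcd"), columns=list("abcd"))
        _, groups = ct.lineage_dendrogram(corr, n_groups=2)
        assert groups["a"] == groups["b"] != groups["c"]
        assert groups["c"] == groups["d"]

    def test_leaf_count_and_errors(self):
        rng = np.random.default_rng(1)
        m = rng.random((6, 6))
        corr = pd.DataFrame((m + m.T) / 2, index=range(6), columns=range(6))
        Z, _ = ct.lineage_dendrogram(corr)
        assert Z.shape[0] == 5  # n-1 merges -> n leaves
        with pytest.raises(ValueError):
            ct.lineage_dendrogram(corr.iloc[:1, :1])


class TestCloneComposition:
    def test_categories(self):
        table, ann = make_instance({
            # clone G: all astrocytes
            "g1": ("G", "x", "astrocyte"), "g2": ("G", "x", "astrocyte"),
            # clone M: 5 neurons + 1 astrocyte -> 5/6 in (0.8, 1) -> ">80%", mixed
            **{f"m{i}": ("M", "x", "neuron") for i in range(5)},
            "m5": ("M", "x", "astrocyte"),
            # clone H: 4 neurons + 4 astrocytes -> 0.5 -> "<80%", mixed
            **{f"h{i}": ("H", "x", "neuron") for i in range(4)},
            **{f"h{i+4}": ("H", "x", "astrocyte") for i in range(4)},
            # clone V: vascular only -> excluded from glia/neuron fractions
            "v1": ("V", "x", "vascular"),
        })
        per_clone, summary = ct.clone_composition(table, ann)
        row = per_clone.set_index("clone")
        assert row.loc["G", "category"] == "100%" and row.loc["G", "lineage"] == "glia_only"
        assert row.loc["M", "dominant_fraction"] == pytest.approx(5 / 6)
        assert row.loc["M", "category"] == ">80%" and row.loc["M", "lineage"] == "mixed"
        assert row.loc["H", "category"] == "<80%" and row.loc["H", "lineage"] == "mixed"
        assert row.loc["V", "lineage"] == "other"
        s = summary.iloc[0]
        assert s["n_other"] == 1
        assert s["frac_glia_only"] + s["frac_neuron_only"] + s["frac_mixed"] == pytest.approx(1.0)

    def test_unclassed_cell_fails(self):
        table, ann = make_instance({"a": ("A", "s1", "neuron"), "b": ("A", "s1")})
        with pytest.raises(ValueError):
            ct.clone_composition(table, ann)


class TestIntersections:
    def test_counts_and_conservation(self):
        table, ann = make_instance({
            "a1": ("A", "s1"), "a2": ("A", "s2"),
            "b1": ("B", "s1"), "b2": ("B", "s2"),
            "c1": ("C", "s1"), "c2": ("C", "s3"),
            "d1": ("D", "s1"),
        })
        inter, sizes = ct.clone_intersections(table, ann, ["s1", "s2", "s3"])
        got = dict(zip(inter["states"], inter["n_clones"]))
        assert got == {"s1&s2": 2, "s1&s3": 1, "s1": 1}
        assert inter["n_clones"].sum() == 4
        assert sizes["s1"] == 4

    def test_dispersing_only_drops_single_state_clones(self):
        table, ann = make_instance({"d1": ("D", "s1"), "a1": ("A", "s1"), "a2": ("A", "s2")})
        inter, _ = ct.clone_intersections(table, ann, ["s1", "s2"], dispersing_only=True)
        assert dict(zip(inter["states"], inter["n_clones"])) == {"s1&s2": 1}

    def test_empty_selection_fails(self):
        table, ann = make_instance({"a": ("A", "s1"), "b": ("A", "s2")})
        with pytest.raises(ValueError):
            ct.clone_intersections(table, ann, [])
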