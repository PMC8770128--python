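"""STICR processing: extraction, mismatch-tolerant alignment, directional
UMI collapse, the tiered dominant-barcode rules, and clone assembly."""

import itertools

import numpy as np
import pytest

import clonetrace as ct
from clonetrace.sticr import ReadLayout, SticrParams

LAYOUT = ReadLayout(fragment_length=4, viral_index_length=2)


class TestExtractFragments:
    def test_identity_extraction(self):
        frags, err = ct.extract_fragments("AAAACCCCGGGGTT", LAYOUT)
        assert err is None
        assert frags == ("AAAA", "CCCC", "GGGG", "TT")

    def test_truncated_rejected(self):
        frags, err = ct.extract_fragments("AAAA", LAYOUT)
        assert frags is None and err == "truncated"

    def test_flanks_ignored(self):
        layout = ReadLayout(fragment_length=4, viral_index_length=2, start=3)
        frags, _ = ct.extract_fragments("TTT" + "AAAACCCCGGGGTT" + "GGGG", layout)
        assert frags == ("AAAA", "CCCC", "GGGG", "TT")


class TestAlignFragment:
    POOL = ("AAAAAAAA", "AAAATTTT", "GGGGGGGG")

    def test_exact_match(self):
        assert ct.align_fragment("AAAAAAAA", self.POOL) == 0

    def test_two_mismatches_accepted(self):
        assert ct.align_fragment("AAAAAAGG", self.POOL) == 0

    def test_beyond_threshold_is_none(self):
        assert ct.align_fragment("TTTAAAAA", self.POOL) == "none"  # distance 3 to best

    def test_tie_is_ambiguous(self):
        # distance 2 to both pool[0] and pool[1]
        assert ct.align_fragment("AAAATTAA", self.POOL) == "ambiguous"

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ct.align_fragment("AAA", self.POOL)


class TestDedupUmis:
    def _counts(self, triples, mm=1):
        df = ct.dedup_umis(triples, SticrParams(umi_collapse_mismatch=mm))
        return dict(zip(zip(df["cell_id"], df["barcode_id"]), df["umi_count"]))

    def test_exact_duplicates_collapse(self):
        out = self._counts([("c", "AAAA", "B", 1), ("c", "AAAA", "B", 1)])
        assert out == {("c", "B"): 1}

    def test_hamming1_merges_into_dominant(self):
        out = self._counts([("c", "AAAA", "B", 10), ("c", "AAAT", "B", 1)])
        assert out == {("c", "B"): 1}

    def test_two_star_clusters_survive_as_two(self):
        triples = [
            ("c", "AAAA", "B", 9), ("c", "AAAT", "B", 1), ("c", "AATA", "B", 1),
            ("c", "GGGG", "B", 8), ("c", "GGGT", "B", 1), ("c", "GGTG", "B", 1),
        ]
        assert self._counts(triples) == {("c", "B"): 2}

    def test_zero_mismatch_keeps_distinct(self):
        out = self._counts([("c", "AAAA", "B", 5), ("c", "AAAT", "B", 5)], mm=0)
        assert out == {("c", "B"): 2}

    def test_empty_input(self):
        assert ct.dedup_umis([]).empty

    def test_matches_connected_merge_oracle(self):
        # brute force: survivors = one per connected component after
        # repeatedly absorbing any <=1-mismatch neighbour of a seed whose
        # count is not larger, seeds in (count desc, lex) order
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(2, 12)
            umis = {"".join(rng.choice(list("ACGT"), 4)): int(rng.integers(1, 20))
                    for _ in range(n)}
            triples = [("c", u, "B", k) for u, k in umis.items()]
            got = self._counts(triples)[("c", "B")]

            def ham(a, b):
                return sum(x != y for x, y in zip(a, b))

            left = dict(umis)
            survivors = 0
            while left:
                seed = sorted(left, key=lambda u: (-left[u], u))[0]
                survivors += 1
                cluster = {seed}
                grew = True
                while grew:
                    grew = False
                    for u in list(left):
                        if u in cluster:
                            continue
                        if any(ham(u, m) <= 1 and left[u] <= left[m] for m in cluster):
                            cluster.add(u)
                            grew = True
                for u in cluster:
                    left.pop(u)
            assert got == survivors


class TestDominantBarcode:
    @pytest.mark.parametrize(
        "counts,expect",
        [
            ({"B1": 10}, ("B1", 1)),            # single candidate, passes final
            ({"B1": 25, "B2": 5}, ("B1", 2)),   # 25 >= 5*5 -> dominant
            ({"B1": 8}, None),                  # candidate but < 9 final UMIs
            ({"B1": 20, "B2": 6}, None),        # 20 < 5*6 -> no dominant
            ({"B1": 4, "B2": 3}, None),         # no candidate at >= 5
            ({"B1": 9, "B2": 4}, ("B1", 1)),    # one candidate; sub-threshold rival
            ({"B1": 45, "B2": 9}, ("B1", 2)),   # 45 >= 5*9
        ],
    )
    def test_decision_table(self, counts, expect):
        call = ct.assign_clonal_barcode(counts, cell_id="c")
        if expect is None:
            assert call is None
        else:
            assert (call.barcode_id, call.tier) == expect

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            ct.assign_clonal_barcode({"B1": 0})


class TestCloneTable:
    def _call(self, cell, bc, ds="A", tier=1):
        return ct.BarcodeCall(cell_id=cell, barcode_id=bc, umi_count=10, tier=tier, dataset=ds)

    def test_shared_barcode_forms_clone(self):
        table = ct.build_clone_table([self._call(f"c{i}", "X") for i in range(3)])
        assert [len(v) for v in table.clones.values()] == [3]

    def test_cross_dataset_blacklist(self):
        calls = [self._call("c1", "Y", "A"), self._call("c2", "Y", "B"),
                 self._call("c3", "Z", "A")]
        table = ct.build_clone_table(calls)
        assert {table.barcode_of[k] for k in table.clones} == {"Z"}

    def test_tier_policy(self):
        calls = [self._call("c1", "X", tier=1), self._call("c2", "X", tier=2)]
        assert sum(len(v) for v in ct.build_clone_table(calls).clones.values()) == 1
        both = ct.build_clone_table(calls, tier_policy="tier1_and_2")
        assert sum(len(v) for v in both.clones.values()) == 2

    def test_conflicting_cell_fails(self):
        with pytest.raises(ValueError):
            ct.build_clone_table([self._call("c1", "X"), self._call("c1", "Y")])

    def test_round_trip_frame(self):
        table = ct.build_clone_table([self._call(f"c{i}", "X") for i in range(3)])
        again = ct.CloneTable.from_frame(table.to_frame())
        assert again.clone_of() == table.clone_of()


class TestCloneSizeSummary:
    def test_constant_sizes(self):
        table = ct.CloneTable.from_clone_map(
            {f"c{i}": f"k{i % 3}" for i in range(9)}
        )
        row = ct.clone_size_summary(table).iloc[0]
        assert (row["mean_size"], row["sem_size"], row["max_size"]) == (3.0, 0.0, 3)

    def test_hand_sem(self):
        clone_of = {"a": "k1", "b": "k1", "c": "k2", "d": "k2", "e": "k2", "f": "k2"}
        row = ct.clone_size_summary(ct.CloneTable.from_clone_map(clone_of)).iloc[0]
        # sizes {2, 4}: sd = sqrt(2), sem = sd/sqrt(2) = 1
        assert row["mean_size"] == 3.0 and row["sem_size"] == pytest.approx(1.0)
        assert row["max_size"] == 4

    def test_all_singletons(self):
        table = ct.CloneTable.from_clone_map({f"c{i}": f"k{i}" for i in range(4)})
        row = ct.clone_size_summary(table).iloc[0]
        assert row["n_multicellular"] == 0 and row["n_singleton"] == 4


class TestEndToEnd:
    def test_noiseless_recovery(self, small_library, sticr_population):
        from conftest import recovery_ari

        reads = ct.gen_reads(sticr_population, small_library, seed=3)
        ref = ct.FragmentReference.from_library(small_library)
        _, table, funnel = ct.call_sticr_clones(reads.records, ref)
        ari, n = recovery_ari(sticr_population, reads, table)
        assert n == len(sticr_population.cells)
        assert ari == 1.0
        assert funnel["records_aligned"] == funnel["records_in"]

    def test_monotone_in_final_threshold(self, small_library, sticr_population):
        reads = ct.gen_reads(
            sticr_population, small_library,
            umi_per_molecule_dist=("poisson", 9.0), seed=3,
        )
        ref = ct.FragmentReference.from_library(small_library)
        kept = []
        for thr in (9, 12, 15):
            params = SticrParams(min_umi_final=thr)
            _, table, _ = ct.call_sticr_clones(reads.records, ref, params)
            kept.append(sum(len(v) for v in table.clones.values()))
        assert kept == sorted(kept, reverse=True)
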