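"""Generalized Landau-Vishkin extension over variation-tree paths."""

import edlib
import numpy as np
import pytest

from varatree.refvar import encode_read
from varatree.vara import (
    PathState,
    PruneConfig,
    lv_edit_distance,
    prune_path,
    select_longest,
    vara_align,
)
from conftest import dele, ins, ref_from, tree_of
from oracles import dp_edit, dp_edit_str, read_bits


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestLvEditDistance:
    @pytest.mark.parametrize(
        "a,b,emax,expect",
        [
            ("AAAA", "AAAA", 2, 0),
            ("GCGTATGC", "GCTATGC", 2, 1),
            ("ACGT", "TGCA", 1, None),
            ("", "", 3, 0),
            ("A", "", 3, 1),
        ],
    )
    def test_examples(self, a, b, emax, expect):
        assert lv_edit_distance(a, b, emax) == expect

    def test_against_full_dp_and_edlib(self):
        rng = np.random.default_rng(9)
        for _ in range(400):
            n = int(rng.integers(0, 60))
            a = rand_seq(rng, n)
            b = list(a)
            for _ in range(int(rng.integers(0, 6))):
                op = rng.choice(["sub", "ins", "del"])
                if op == "sub" and b:
                    b[int(rng.integers(0, len(b)))] = "ACGT"[int(rng.integers(0, 4))]
                elif op == "ins":
                    b.insert(int(rng.integers(0, len(b) + 1)), "ACGT"[int(rng.integers(0, 4))])
                elif b:
                    b.pop(int(rng.integers(0, len(b))))
            b = "".join(b)
            truth = dp_edit_str(a, b)
            if a and b:
                assert truth == edlib.align(a, b)["editDistance"]
            got = lv_edit_distance(a, b, 8)
            assert got == (truth if truth <= 8 else None)


class TestVaraAlignExamples:
    def test_linear_exact(self):
        t = tree_of("ACGT")
        res = vara_align(t, "ACGT", PruneConfig(e_max=2))
        assert len(res.alignments) == 1
        c = res.alignments[0]
        assert (c.e, str(c.alt_cigar)) == (0, "4M")

    def test_deletion_path_beats_variant_free(self):
        t = tree_of("ACGTACGT", [dele("c", 4, "AC", 0)])
        res = vara_align(t, "ACGTGT", PruneConfig(e_max=4, exhaustive=True))
        by_vids = {}
        for c in res.alignments:
            by_vids[c.variant_ids] = min(by_vids.get(c.variant_ids, 99), c.e)
        assert by_vids[(0,)] == 0
        assert by_vids[()] == 2
        assert res.alignments[0].variant_ids == (0,)  # least-e output first

    def test_insertion_path_with_one_mismatch(self):
        t = tree_of("ACGT", [ins("c", 2, "TT", 0)])
        res = vara_align(t, "ACTAGT", PruneConfig(e_max=3))
        assert res.alignments[0].e == 1
        assert res.alignments[0].variant_ids == (0,)

    def test_emitted_cigar_consumes_read(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            seq = rand_seq(rng, 40)
            ref = ref_from({"c": seq})
            vs = [ins("c", 10, rand_seq(rng, 3), 0), dele("c", 20, seq[20:23], 1)]
            t = tree_of(seq, vs, ref=ref)
            read = t.paths[int(rng.integers(0, 4))].hap_seq[:30]
            res = vara_align(t, read, PruneConfig(e_max=4))
            for c in res.alignments:
                assert c.alt_cigar.read_len == len(read)
                assert c.alt_cigar.ref_len == c.hap_end - c.hap_start


class TestSelectLongest:
    def test_longest_wins(self):
        best = select_longest([(1, 5, 9), (1, 7, 11)])
        assert best[(1, 0)] == (1, 7, 11)

    def test_single_hit(self):
        assert select_longest([(1, 5, 9)])[(1, 0)] == (1, 5, 9)

    def test_distinct_ids_kept(self):
        best = select_longest([(1, 7, 9), (2, 7, 9)])
        assert set(best) == {(1, 0), (2, 0)}

    def test_tie_prefers_smaller_resume(self):
        best = select_longest([(1, 7, 12), (1, 7, 9)])
        assert best[(1, 0)] == (1, 7, 9)


class TestPrunePath:
    def _vars(self, n, length):
        return tuple(ins("c", 10 * i, "A" * length, i) for i in range(n))

    def test_four_large_on_100bp_pruned(self):
        st = PathState(e=0, read_len=100, taken=self._vars(4, 4))
        assert prune_path(st, PruneConfig(e_max=6)) is True

    def test_three_large_on_100bp_kept(self):
        st = PathState(e=0, read_len=100, taken=self._vars(3, 4))
        assert prune_path(st, PruneConfig(e_max=6)) is False

    def test_small_variants_not_counted(self):
        st = PathState(e=0, read_len=100, taken=self._vars(6, 2))
        assert prune_path(st, PruneConfig(e_max=6)) is False

    def test_no_variants_within_budget_kept(self):
        assert prune_path(PathState(e=3, read_len=100), PruneConfig(e_max=6)) is False
        assert prune_path(PathState(e=7, read_len=100), PruneConfig(e_max=6)) is True


class TestDegenerateEquality:
    def test_zero_variants_equals_lv_and_dp(self):
        """Global-mode vara on a variant-free window is the classical LV."""
        rng = np.random.default_rng(17)
        for _ in range(200)            :
            n = int(rng.integers(5, 60))
            window = rand_seq(rng, n)
            read = list(window)
            for _ in range(int(rng.integers(0, 5))):
                op = rng.choice(["sub", "ins", "del"])
                if op == "sub":
                    read[int(rng.integers(0, len(read)))] = "ACGT"[int(rng.integers(0, 4))]
                elif op == "ins":
                    read.insert(int(rng.integers(0, len(read) + 1)), "ACGT"[int(rng.integers(0, 4))])
                elif len(read) > 1:
                    read.pop(int(rng.integers(0, len(read))))
            read = "".join(read)
            truth = dp_edit_str(read, window)
            lv = lv_edit_distance(read, window, 8)
            t = tree_of(window)
            res = vara_align(t, read, PruneConfig(e_max=8, mode="global"))
            got = res.alignments[0].e if res.alignments else None
            assert lv == (truth if truth <= 8 else None)
            assert got == lv


class TestOracleEquivalence:
    def _random_instance(self, rng):
        n = int(rng.integers(50, 201))
        seq = rand_seq(rng, n)
        ref = ref_from({"c": seq})
        vs = []
        pos = int(rng.integers(2, 10))
        vid = 0
        nv = int(rng.integers(0, 6))
        while vid < nv and pos < n - 10:
            ln = int(rng.integers(1, 9))
            if rng.random() < 0.5:
                vs.append(ins("c", pos, rand_seq(rng, ln), vid))
            else:
                vs.append(dele("c", pos, seq[pos : pos + ln], vid))
            vid += 1
            pos += ln + 2 + int(rng.integers(0, n // 6))
        t = tree_of(seq, vs, ref=ref)
        src = t.paths[int(rng.integers(0, len(t.paths)))]
        L = int(rng.integers(30, min(len(src.hap_seq), 120) + 1))
        read = list(src.hap_seq[:L])
        e_max = 6
        for _ in range(int(rng.integers(0, e_max + 1))):
            op = rng.choice(["sub", "ins", "del"])
            if op == "sub":
                read[int(rng.integers(0, len(read)))] = "ACGT"[int(rng.integers(0, 4))]
            elif op == "ins":
                read.insert(int(rng.integers(0, len(read) + 1)), "ACGT"[int(rng.integers(0, 4))])
            elif len(read) > 5:
                read.pop(int(rng.integers(0, len(read))))
        return t, "".join(read), e_max

    def test_min_e_equals_brute_force(self):
        """Smaller-scale version of the core oracle-equivalence property."""
        rng = np.random.default_rng(2024)
        cfg_kw = dict(large_variant_len=10_000)  # heuristic off for the oracle
        for _ in range(150):
            t, read, e_max = self._random_instance(rng)
            res = vara_align(t, read, PruneConfig(e_max=e_max, **cfg_kw))
            rb = read_bits(read)
            oracle = min(dp_edit(rb, p.hap_masks) for p in t.paths)
            if oracle <= e_max:
                assert res.alignments and res.alignments[0].e == oracle
                win = t.path(res.alignments[0].path_id)
                assert dp_edit(rb, win.hap_masks) == oracle
            else:
                assert not res.alignments

    def test_monotone_in_variants(self):
        """Adding a variant to the tree never increases the minimal e."""
        rng = np.random.default_rng(55)
        for _ in range(60):
            n = 80
            seq = rand_seq(rng, n)
            ref = ref_from({"c": seq})
            v0 = dele("c", 30, seq[30:33], 0)
            v1 = ins("c", 55, rand_seq(rng, 4), 1)
            t_small = tree_of(seq, [v0], ref=ref)
            t_big = tree_of(seq, [v0, v1], ref=ref)
            read = t_big.paths[-1].hap_seq[:60]
            cfg = PruneConfig(e_max=8, large_variant_len=10_000)
            e_small = min(
                (c.e for c in vara_align(t_small, read, cfg).alignments), default=99
            )
            e_big = min(
                (c.e for c in vara_align(t_big, read, cfg).alignments), default=99
            )
            assert e_big <= e_small

    def test_path_cap_overflow_prunes_and_continues(self):
        from varatree.vartree import RegionWindow, build_tree

        ref = ref_from({"c": "ACGT" * 100})
        seq = ref.decode("c")
        vs = [ins("c", 10 + 3 * i, "C", i) for i in range(40)]
        t = build_tree([(RegionWindow("c", 0, 400), ref.codes("c"))], variants=[vs])
        res = vara_align(t, seq[:60], PruneConfig(e_max=3, path_cap=100))
        assert res.pruned is True
        assert res.alignments and res.alignments[0].e == 0

    def test_cell_update_guard(self):
        rng = np.random.default_rng(8)
        t, read, e_max = self._random_instance(rng)
        res = vara_align(t, read, PruneConfig(e_max=e_max, large_variant_len=10_000))
        assert res.cell_updates <= 4 * (e_max + 1) ** 2 * len(t.paths)
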