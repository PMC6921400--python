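"""Seeding, extension dispatch, mate anchoring and SAM emission."""

import numpy as np
import pytest

from varatree.mapper import (
    InsertModel,
    MapperConfig,
    PairMapper,
    SeedHit,
    anchor_mate,
    build_seed_index,
    collect_seeds,
    map_paired_end,
)
from varatree.cigar import validate_cigar
from varatree.refvar import integrate_variants, revcomp
from varatree.simgen import (
    SimConfig,
    evaluate_alignments,
    simulate_genome,
    simulate_reads,
    simulate_variants,
    write_fastq_pair,
)
from conftest import dele, ins, ref_from, snp


def rand_ref(rng, n, name="chr1"):
    return ref_from({name: "".join(rng.choice(list("ACGT"), n))})


class TestSeedIndex:
    def test_positions_found(self):
        ref = ref_from({"c": "ACGTACGT"})
        idx = build_seed_index(ref, k=4, repeat_cap=64)
        assert idx.lookup("ACGT") == [(0, 0), (0, 4)]
        assert idx.lookup("TTTT") == ()

    def test_repeat_cap_flags(self):
        ref = ref_from({"c": "ACGTACGTACGTAA"})
        idx = build_seed_index(ref, k=4, repeat_cap=2)
        assert idx.lookup("ACGT") == ()  # 3 occurrences > cap
        assert "ACGT" in idx.flagged

    def test_non_acgt_kmers_skipped(self):
        ref = ref_from({"c": "ACGTNACGT"})
        idx = build_seed_index(ref, k=4, repeat_cap=64)
        assert idx.lookup("ACGT") == [(0, 0), (0, 5)]
        assert all("N" not in kmer for kmer in idx.table)

    def test_k_bounds(self):
        from varatree.mapper import SeedIndex

        with pytest.raises(ValueError):
            SeedIndex(3, 2)
        with pytest.raises(ValueError):
            SeedIndex(40, 2)


class TestCollectSeeds:
    def test_identity_read(self):
        rng = np.random.default_rng(0)
        ref = rand_ref(rng, 2000)
        idx = build_seed_index(ref)
        read = ref.decode("chr1", 500, 600)
        hits = collect_seeds(read, idx)
        assert any(h.pos - h.read_off == 500 and h.strand == "+" for h in hits)

    def test_reverse_strand(self):
        rng = np.random.default_rng(1)
        ref = rand_ref(rng, 2000)
        idx = build_seed_index(ref)
        read = revcomp(ref.decode("chr1", 500, 600))
        hits = collect_seeds(read, idx)
        assert any(h.strand == "-" and h.pos - h.read_off == 500 for h in hits)

    def test_all_n_read(self):
        rng = np.random.default_rng(2)
        ref = rand_ref(rng, 500)
        idx = build_seed_index(ref)
        assert collect_seeds("N" * 50, idx) == []

    def test_central_mismatch_leaves_flank_seeds(self):
        rng = np.random.default_rng(3)
        ref = rand_ref(rng, 5000)
        idx = build_seed_index(ref)
        read = list(ref.decode("chr1", 1000, 1100))
        read[50] = "ACGT"[("ACGT".index(read[50]) + 1) % 4]
        hits = collect_seeds("".join(read), idx)
        assert any(h.pos - h.read_off == 1000 for h in hits)


class TestAnchorMate:
    def test_window_arithmetic(self):
        h = SeedHit(0, "c", 10_000, 16, "+")
        (w,) = anchor_mate([h], InsertModel(500, 25, 4), 100)
        assert (w.start, w.end) == (10_300, 10_700)

    def test_zero_sd_window_width(self):
        h = SeedHit(0, "c", 10_000, 16, "+")
        (w,) = anchor_mate([h], InsertModel(500, 0, 4), 100)
        assert w.end - w.start == 200

    def test_clamped_to_chromosome(self):
        h = SeedHit(0, "c", 100, 16, "-")
        ws = anchor_mate([h], InsertModel(500, 25, 4), 100, chrom_len=1000)
        assert all(w.start >= 0 and w.end <= 1000 for w in ws)


def _pipeline(rng, n=20_000, variants=None, **simkw):
    cfg = SimConfig(genome_length=n, n_pairs=0, seed=int(rng.integers(1 << 30)), **simkw)
    genome = simulate_genome(cfg)
    ref = ref_from(genome)
    vs = variants(genome) if callable(variants) else (variants or [])
    ref2, altseq = integrate_variants(ref, vs)
    return cfg, genome, ref2, altseq


class TestNeedsVara:
    def setup_method(self):
        rng = np.random.default_rng(42)
        self.cfg, self.genome, self.ref, _ = _pipeline(rng)
        seq = self.genome["chr1"]
        vs = [ins("chr1", 5_000, "ACGTACGTACG", 0)]  # 11 bp insertion
        self.ref, self.altseq = integrate_variants(self.ref, vs)
        self.pm = PairMapper(self.ref, self.altseq)
        self.seq = seq

    def _hits(self, read):
        return collect_seeds(read, self.pm.index, self.pm.cfg.stride)

    def test_perfect_pair_false(self):
        r1 = self.seq[2000:2100]
        r2 = revcomp(self.seq[2400:2500])
        pair = (r1, r2)
        hits = (self._hits(r1), self._hits(r2))
        assert self.pm.needs_vara(pair, hits) is False

    def test_insertion_spanning_end_true(self):
        hap = self.seq[4950:5000] + "ACGTACGTACG" + self.seq[5000:5050]
        r1 = hap[:100]
        r2 = revcomp(self.seq[5300:5400])
        hits = (self._hits(r1), self._hits(r2))
        assert self.pm.needs_vara((r1, r2), hits) is True

    def test_single_mismatch_false(self):
        r1 = list(self.seq[2000:2100])
        r1[50] = "ACGT"[("ACGT".index(r1[50]) + 1) % 4]
        r1 = "".join(r1)
        r2 = revcomp(self.seq[2400:2500])
        hits = (self._hits(r1), self._hits(r2))
        assert self.pm.needs_vara((r1, r2), hits) is False


class TestExtendWithVara:
    def test_seed_covering_whole_read(self):
        rng = np.random.default_rng(7)
        _, genome, ref, altseq = _pipeline(rng)
        seq = genome["chr1"]
        pm = PairMapper(ref, altseq)
        read = seq[3000:3100]
        (c,) = pm.extend_with_vara(SeedHit(0, "chr1", 3000, 16, "+"), read)
        assert (c.pos, c.e, str(c.cigar)) == (3000, 0, "100M")

    def test_planted_deletion_right_of_seed(self):
        rng = np.random.default_rng(8)
        _, genome, base_ref, _ = _pipeline(rng)
        seq = genome["chr1"]
        d = dele("chr1", 3050, seq[3050:3053], 0)
        ref, altseq = integrate_variants(base_ref, [d])
        pm = PairMapper(ref, altseq)
        read = seq[3000:3050] + seq[3053:3103]  # takes the deletion
        (c,) = pm.extend_with_vara(SeedHit(0, "chr1", 3000, 16, "+"), read)
        assert c.e == 0
        assert c.variant_ids == (0,)
        assert "3D" in str(c.cigar)
        # without variant knowledge the deletion costs 3 edits
        ref0, alt0 = integrate_variants(base_ref, [])
        pm0 = PairMapper(ref0, alt0)
        (c0,) = pm0.extend_with_vara(SeedHit(0, "chr1", 3000, 16, "+"), read)
        assert c0.e >= 3 or c0.clip > 0

    def test_chromosome_start_truncates_window(self):
        rng = np.random.default_rng(9)
        _, genome, ref, altseq = _pipeline(rng)
        seq = genome["chr1"]
        read = seq[0:100]
        pm = PairMapper(ref, altseq)
        (c,) = pm.extend_with_vara(SeedHit(40, "chr1", 40, 16, "+"), read)
        assert (c.pos, c.e) == (0, 0)


class TestSelectOptimalAndSam:
    def _map(self, tmp_path, pairs_data, genome, variants=()):
        ref = ref_from(genome)
        ref2, altseq = integrate_variants(ref, list(variants))
        write_fastq_pair(pairs_data, tmp_path / "r1.fq", tmp_path / "r2.fq")
        sam = tmp_path / "out.sam"
        stats = map_paired_end(ref2, altseq, tmp_path / "r1.fq", tmp_path / "r2.fq", sam)
        import pysam

        with pysam.AlignmentFile(str(sam), "r") as fh:
            recs = list(fh)
        return recs, stats

    def test_unique_proper_pair_flags_and_mapq(self, tmp_path):
        rng = np.random.default_rng(11)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 20_000))}
        seq = genome["chr1"]
        pairs = [("p0", seq[1000:1100], revcomp(seq[1400:1500]), "I" * 100)]
        recs, _ = self._map(tmp_path, pairs, genome)
        assert [r.flag for r in recs] == [99, 147]
        assert all(r.mapping_quality == 60 for r in recs)
        assert recs[0].reference_start == 1000
        assert recs[1].reference_start == 1400
        assert recs[0].template_length == 500
        assert recs[1].template_length == -500

    def test_ambiguous_locus_gets_mapq_zero(self, tmp_path):
        rng = np.random.default_rng(12)
        unit = "".join(rng.choice(list("ACGT"), 3000))
        genome = {"chr1": unit + unit}  # exact duplication
        seq = genome["chr1"]
        pairs = [("p0", seq[100:200], revcomp(seq[500:600]), "I" * 100)]
        recs, _ = self._map(tmp_path, pairs, genome)
        assert all(r.mapping_quality == 0 for r in recs)

    def test_unmapped_pair(self, tmp_path):
        rng = np.random.default_rng(13)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 5000))}
        other = "".join(np.random.default_rng(99).choice(list("ACGT"), 100))
        pairs = [("p0", other, revcomp(other), "I" * 100)]
        recs, stats = self._map(tmp_path, pairs, genome)
        assert all(r.is_unmapped for r in recs)
        assert stats.unmapped_ends == 2

    def test_mate_rescue_by_insert_anchor(self, tmp_path):
        # mate 2 lies inside a high-copy repeat: every one of its k-mers is
        # repeat-flagged, so genome-wide seeding fails and only the insert-
        # anchored window search can place it (next to its unique mate 1)
        rng = np.random.default_rng(14)
        unique_l = "".join(rng.choice(list("ACGT"), 2000))
        unit = "".join(rng.choice(list("ACGT"), 200))
        unique_r = "".join(rng.choice(list("ACGT"), 2000))
        genome = {"chr1": unique_l + unit * 70 + unique_r}
        seq = genome["chr1"]
        r1_start = 1850
        m2_start = r1_start + 500 - 100  # inside the first repeat copies
        pairs = [
            ("p0", seq[r1_start : r1_start + 100],
             revcomp(seq[m2_start : m2_start + 100]), "I" * 100)
        ]
        recs, stats = self._map(tmp_path, pairs, genome)
        r2 = [r for r in recs if r.is_read2][0]
        assert not r2.is_unmapped
        assert abs(r2.reference_start - m2_start) <= 10
        assert stats.rescued_ends == 1

    def test_every_emitted_cigar_validates(self, tmp_path):
        rng = np.random.default_rng(15)
        cfg = SimConfig(genome_length=30_000, n_pairs=300, seed=5)
        genome = simulate_genome(cfg)
        variants = simulate_variants(genome, cfg)
        pairs, truth = simulate_reads(genome, variants, cfg)
        recs, _ = self._map(tmp_path, pairs, genome, variants)
        assert len(recs) == 600
        for r in recs:
            if r.is_unmapped:
                continue
            assert validate_cigar(r.cigarstring, len(r.query_sequence),
                                  r.reference_end - r.reference_start)
            assert 0 <= r.reference_start < 30_000
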