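"""End-to-end paired-end alignment.

Seeding uses a plain k-mer hash over the reference with stride sampling and
a repeat cap (the novelty of the method is the extension stage, not
seeding).  Seed hits are chained per diagonal, extended exactly with
SNP-tolerant matching, and only when the exact chain leaves enough of the
read unexplained — typically because the read spans a known INDEL — is the
variation tree built and the generalized Landau-Vishkin extension (VARA)
invoked on each side of the seed.  Reads explained up to a few mismatches
use the same extension kernel on a variant-free window, which degenerates
to the classical banded algorithm.

Mates are paired by FR orientation and insert size; a one-sided pair is
rescued by anchoring a search window on the mapped end via the insert
model.  CIGARs are restored to reference coordinates before SAM emission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cigar import CigarString, compose_ref_cigar
from .errors import CigarCompositionError
from .refvar import AltSeqIndex, VarAwareReference, VType, encode_read, revcomp
from .vara import PruneConfig, default_e_max, vara_align
from .vartree import RegionWindow, build_tree
from .vatr import match_run

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InsertModel:
    """Insert-size model for proper-pair calls and mate anchoring."""

    mean: float = 500.0
    sd: float = 25.0
    w: float = 4.0  # window half-width in units of sd

    def __post_init__(self):
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("insert mean must be > 0 and sd >= 0")


@dataclass
class MapperConfig:
    k: int = 16
    stride: int = 8
    repeat_cap: int = 64
    e_max: int | None = None  # None -> 6% of read length
    min_unexplained_for_vara: int = 5  # "g": exact-chain gap that triggers VARA
    window_margin: int = 50  # extra window length so deletions can finish beyond
    max_loci: int = 4
    insert: InsertModel = field(default_factory=InsertModel)
    max_variants_per_path: int = 6
    path_cap: int = 4096
    mapq_cap: int = 60

    def resolve_e_max(self, read_len: int) -> int:
        return self.e_max if self.e_max is not None else default_e_max(read_len)


@dataclass(frozen=True)
class SeedHit:
    read_off: int
    chrom: str
    pos: int
    length: int
    strand: str


class SeedIndex:
    """k-mer -> sorted reference positions, with a repeat cap.

    k-mers occurring more often than ``repeat_cap`` are flagged and never
    returned; k-mers containing non-ACGT bases are not indexed.
    """

    def __init__(self, k: int, repeat_cap: int):
        if not 4 <= k <= 31:
            raise ValueError("k must be in [4, 31]")
        self.k = k
        self.repeat_cap = repeat_cap
        self.table: dict[str, list[tuple[int, int]]] = {}
        self.flagged: set[str] = set()
        self.chrom_names: list[str] = []

    def lookup(self, kmer: str):
        """Hits as (chrom index, position) tuples, or () if absent/flagged."""
        return self.table.get(kmer, ())


def build_seed_index(ref: VarAwareReference, k: int = 16, repeat_cap: int = 64) -> SeedIndex:
    idx = SeedIndex(k, repeat_cap)
    idx.chrom_names = ref.names
    table = idx.table
    for ci, name in enumerate(ref.names):
        seq = ref.decode(name)
        # positions whose k-mer window contains a non-ACGT base are skipped
        bad = np.frombuffer(seq.encode(), np.uint8)
        valid = (
            (bad == ord("A")) | (bad == ord("C")) | (bad == ord("G")) | (bad == ord("T"))
        )
        run_ok = np.convolve(valid.astype(np.int32), np.ones(k, np.int32), "valid") == k
        for i in np.nonzero(run_ok)[0]:
            i = int(i)
            kmer = seq[i : i + k]
            slot = table.get(kmer)
            if slot is None:
                table[kmer] = [(ci, i)]
            elif len(slot) <= repeat_cap:
                slot.append((ci, i))
    for kmer, slot in list(table.items()):
        if len(slot) > repeat_cap:
            idx.flagged.add(kmer)
            del table[kmer]
    return idx


def _offsets(read_len: int, k: int, stride: int) -> list[int]:
    offs = list(range(0, read_len - k + 1, stride))
    if offs and offs[-1] != read_len - k:
        offs.append(read_len - k)
    return offs


def collect_seeds(read: str, index: SeedIndex, stride: int = 8) -> list[SeedHit]:
    """Sampled k-mer hits of both strands of ``read``."""
    k = index.k
    if len(read) < k:
        return []
    hits = []
    for strand, s in (("+", read), ("-", revcomp(read))):
        for off in _offsets(len(s), k, stride):
            for ci, p in index.lookup(s[off : off + k]):
                hits.append(SeedHit(off, index.chrom_names[ci], p, k, strand))
    return hits


def anchor_mate(
    hits, insert_model: InsertModel, read_len: int, chrom_len: int | None = None
) -> list[RegionWindow]:
    """Mate-search windows anchored on the mapped end's hits.

    For a forward hit at ``pos`` the reverse mate is expected around
    ``pos + mean``; the window is ``mean +/- w*sd`` widened by a read length
    on both sides (mirrored for reverse hits).  Windows are clamped to the
    chromosome.
    """
    out = []
    m, half = insert_model.mean, insert_model.w * insert_model.sd
    for h in hits:
        if h.strand == "+":
            lo = h.pos + m - half - read_len
            hi = h.pos + m + half + read_len
            side = "R"
        else:
            lo = h.pos + read_len - m - half - read_len
            hi = h.pos + read_len - m + half + read_len
            side = "L"
        lo = int(max(0, lo))
        hi = int(hi if chrom_len is None else min(chrom_len, hi))
        if hi - lo >= 1:
            out.append(RegionWindow(h.chrom, lo, hi, side=side, strand=h.strand))
    return out


@dataclass
class Candidate:
    """One reference-coordinate alignment of a single end."""

    chrom: str
    pos: int
    strand: str
    cigar: CigarString
    e: int  # unexplained edits (known variants cost nothing)
    nm: int  # edits against the reference, known variants included
    clip: int
    variant_ids: tuple[int, ...] = ()

    @property
    def score(self) -> int:
        return self.e + self.clip

    @property
    def ref_end(self) -> int:
        return self.pos + self.cigar.ref_len


@dataclass
class _Side:
    e: int = 0
    clip: int = 0
    cigar: CigarString = field(default_factory=CigarString)
    pos: int = -1  # leftmost ref base consumed; -1 when nothing consumed
    ref_end: int = -1
    variant_ids: tuple[int, ...] = ()


@dataclass
class MapStats:
    pairs: int = 0
    seeded_ends: int = 0
    vara_ends: int = 0
    rescued_ends: int = 0
    pruned: int = 0
    unmapped_ends: int = 0
    softclip_records: int = 0

    def as_dict(self):
        return self.__dict__.copy()


class PairMapper:
    """Maps read pairs against a variation-aware reference."""

    def __init__(self, ref: VarAwareReference, altseq: AltSeqIndex, cfg: MapperConfig | None = None,
                 seed_index: SeedIndex | None = None):
        self.ref = ref
        self.altseq = altseq
        self.cfg = cfg or MapperConfig()
        self.index = seed_index or build_seed_index(ref, self.cfg.k, self.cfg.repeat_cap)
        self.stats = MapStats()
        self._masks = {n: ref.codes(n)[0] for n in ref.names}
        self._chars = {
            n: np.frombuffer(ref.decode(n).encode(), np.uint8) for n in ref.names
        }

    # ------------------------------------------------------------ seeding

    def _diag_groups(self, s: str, window: tuple[str, int, int] | None = None):
        """Group sampled k-mer hits of one oriented read by (chrom, diagonal)."""
        k, stride = self.cfg.k, self.cfg.stride
        groups: dict[tuple[str, int], list[int]] = {}
        if len(s) < k:
            return groups
        for off in _offsets(len(s), k, stride):
            for ci, p in self.index.lookup(s[off : off + k]):
                chrom = self.index.chrom_names[ci]
                if window is not None and (
                    chrom != window[0] or not window[1] <= p < window[2]
                ):
                    continue
                groups.setdefault((chrom, p - off), []).append(off)
        if window is not None and not groups:
            # brute probes: locate the mate inside a small anchored window
            chrom, lo, hi = window
            hay = self.ref.decode(chrom, lo, hi)
            for off in (0, (len(s) - k) // 2, len(s) - k):
                probe = s[off : off + k]
                start = 0
                while True:
                    j = hay.find(probe, start)
                    if j < 0:
                        break
                    groups.setdefault((chrom, lo + j - off), []).append(off)
                    start = j + 1
        return groups

    @staticmethod
    def _runs(offs: list[int], k: int) -> list[tuple[int, int]]:
        """Maximal blocks of overlapping sampled k-mers (exact char match)."""
        offs = sorted(set(offs))
        runs = []
        a = b = offs[0]
        for o in offs[1:]:
            if o - b <= k:
                b = o
            else:
                runs.append((a, b + k))
                a = b = o
        runs.append((a, b + k))
        return runs

    def _exact_extend(self, bits: np.ndarray, chrom: str, a: int, b: int, p: int):
        """Widen an exact block [a, b) at ref p by SNP-tolerant matching."""
        masks = self._masks[chrom]
        right = match_run(bits, b, masks, p + (b - a))
        lim = min(a, p)
        left = 0
        if lim:
            ok = (masks[p - lim : p][::-1] & bits[a - lim : a][::-1]) != 0
            left = int(lim if ok.all() else np.argmin(ok))
        return a - left, b + right, p - left

    # ------------------------------------------------------------ extension

    def _extend_side(self, seg: str, side: str, chrom: str, boundary: int,
                     use_variants: bool, read_len: int) -> _Side:
        if not seg:
            return _Side()
        clen = self.ref.length(chrom)
        margin = self.cfg.window_margin
        if side == "L":
            ws, we = max(0, boundary - len(seg) - margin), boundary
        else:
            ws, we = boundary, min(clen, boundary + len(seg) + margin)
        if we - ws < 1:
            return _Side(clip=len(seg))
        vars_ = []
        if use_variants and len(self.altseq):
            vars_ = self.altseq.query(chrom, ws, min(clen, we + 1))
            vars_ = [
                v
                for v in vars_
                if (v.vtype is VType.INS and ws <= v.pos <= we) or (
                    v.vtype is not VType.INS and v.ref_span[1] > ws and v.pos < we
                )
            ]
            if side == "R":  # right windows keep the half-open insertion rule
                vars_ = [v for v in vars_ if not (v.vtype is VType.INS and v.pos == we)]
        w = RegionWindow(chrom, ws, we, side=side)
        tree = build_tree([(w, self.ref.codes(chrom, ws, we))], variants=[vars_])
        cfg = PruneConfig(
            e_max=self.cfg.resolve_e_max(read_len),
            max_variants_per_path=self.cfg.max_variants_per_path,
            path_cap=self.cfg.path_cap,
        )
        res = vara_align(tree, seg, cfg, anchor="right" if side == "L" else "left")
        if res.pruned:
            self.stats.pruned += 1
        cand = res.alignments[0] if res.alignments else res.best_partial
        if cand is None or cand.read_consumed == 0:
            return _Side(clip=len(seg))
        clip = len(seg) - cand.read_consumed
        try:
            pos, cig = compose_ref_cigar(
                cand.alt_cigar, tree.path(cand.path_id), w, hap_start=cand.hap_start
            )
        except CigarCompositionError:
            return _Side(clip=len(seg))
        if clip:
            cig = (
                CigarString([(clip, "S")]) + cig if side == "L" else cig + CigarString([(clip, "S")])
            )
        return _Side(
            e=cand.e,
            clip=clip,
            cigar=cig,
            pos=pos,
            ref_end=pos + cig.ref_len,
            variant_ids=cand.variant_ids,
        )

    def _extend_cluster(self, chrom: str, strand: str, group_list, s: str, bits: np.ndarray):
        k = self.cfg.k
        rl = len(s)
        clen = self.ref.length(chrom)
        # exact blocks per diagonal, SNP-tolerantly widened
        blocks = []  # (length, a, b, p, diag)
        for diag, offs in group_list:
            for ra, rb in self._runs(offs, k)[:4]:
                p = diag + ra
                if p < 0 or diag + rb > clen:
                    continue
                a, b, p = self._exact_extend(bits, chrom, ra, rb, p)
                blocks.append((b - a, a, b, p, diag))
        if not blocks:
            return None
        blocks.sort(key=lambda t: (-t[0], t[3]))
        _, a, b, p, anchor_diag = blocks[0]
        a, b, p = self._trim_block_at_junctions(chrom, a, b, p)
        if b - a == rl:
            cigar = CigarString([(rl, "M")])
            nm = self._count_mismatches(chrom, p, s, 0, rl)
            return Candidate(chrom, p, strand, cigar, 0, nm, 0)
        # unexplained bases measured on the anchor diagonal only: blocks on a
        # shifted diagonal imply an indel, which is VARA's job to resolve
        covered = sorted((x[1], x[2]) for x in blocks if x[4] == anchor_diag)
        un = rl
        end = 0
        for ca, cb in covered:
            un -= max(0, min(cb, rl) - max(ca, end))
            end = max(end, cb)
        use_variants = un >= self.cfg.min_unexplained_for_vara
        if use_variants:
            self.stats.vara_ends += 1
        left = self._extend_side(s[:a], "L", chrom, p, use_variants, rl)
        right = self._extend_side(s[b:], "R", chrom, p + (b - a), use_variants, rl)
        ops = []
        pos = left.pos if left.pos >= 0 else p
        ops.extend(left.cigar.ops)
        if left.ref_end >= 0 and left.ref_end < p:  # deletion taken at the junction
            ops.append((p - left.ref_end, "D"))
        ops.append((b - a, "M"))
        mid_end = p + (b - a)
        if right.pos > mid_end:
            ops.append((right.pos - mid_end, "D"))
        ops.extend(right.cigar.ops)
        cigar = CigarString(ops)
        if cigar.read_len != rl:
            return None  # inconsistent splice; drop the locus
        nm = self._count_mismatches(chrom, pos, s, 0, rl, cigar)
        return Candidate(
            chrom,
            pos,
            strand,
            cigar,
            left.e + right.e,
            nm,
            left.clip + right.clip,
            tuple(sorted(set(left.variant_ids) | set(right.variant_ids))),
        )

    def _trim_block_at_junctions(self, chrom, a, b, p, slack=12):
        """Pull exact-block edges back to nearby insertion junctions.

        An exact block can overrun an insertion point by a few chance-matching
        bases, hiding the junction inside the block where neither side window
        can take the variant; trimming restores the junction to a boundary.
        """
        if not len(self.altseq):
            return a, b, p
        span = b - a
        for v in self.altseq.query(chrom, p, p + span):
            if v.vtype is not VType.INS:
                continue
            dl, dr = v.pos - p, (p + span) - v.pos
            if 0 < dl <= slack and span - dl >= self.cfg.k // 2:
                a, p = a + dl, p + dl
                span = b - a
            elif 0 < dr <= slack and span - dr >= self.cfg.k // 2:
                b -= dr
                span = b - a
        return a, b, p

    def _count_mismatches(self, chrom, pos, s, ri, n, cigar=None):
        chars = self._chars[chrom]
        sarr = np.frombuffer(s.encode(), np.uint8)
        if cigar is None:
            return int((chars[pos : pos + n] != sarr[ri : ri + n]).sum())
        nm = 0
        rp = pos
        for ln, op in cigar.ops:
            if op == "M":
                nm += int((chars[rp : rp + ln] != sarr[ri : ri + ln]).sum())
                rp += ln
                ri += ln
            elif op == "I":
                nm += ln
                ri += ln
            elif op == "D":
                nm += ln
                rp += ln
            else:  # S
                ri += ln
        return nm

    def align_end(self, read: str, window: tuple[str, int, int] | None = None) -> list[Candidate]:
        """All candidate alignments of one read end, best first."""
        cands: dict[tuple[str, str, int], Candidate] = {}
        margin = self.cfg.window_margin
        for strand in "+-":
            s = read if strand == "+" else revcomp(read)
            groups = self._diag_groups(s, window)
            if not groups:
                continue
            bits = encode_read(s)
            # cluster diagonals within an INDEL's reach of each other
            per_chrom: dict[str, list[tuple[int, list[int]]]] = {}
            for (chrom, diag), offs in groups.items():
                per_chrom.setdefault(chrom, []).append((diag, offs))
            clusters = []
            for chrom, dg in per_chrom.items():
                dg.sort()
                cur = [dg[0]]
                for item in dg[1:]:
                    if item[0] - cur[-1][0] <= margin:
                        cur.append(item)
                    else:
                        clusters.append((chrom, cur))
                        cur = [item]
                clusters.append((chrom, cur))
            clusters.sort(key=lambda t: -sum(len(offs) for _, offs in t[1]))
            for chrom, group_list in clusters[: self.cfg.max_loci]:
                c = self._extend_cluster(chrom, strand, group_list, s, bits)
                if c is None:
                    continue
                key = (c.chrom, c.strand, c.pos)
                old = cands.get(key)
                if old is None or c.score < old.score:
                    cands[key] = c
        out = sorted(cands.values(), key=lambda c: (c.score, c.e, c.chrom, c.pos))
        return out

    def needs_vara(self, read_pair, seed_hits) -> bool:
        """Does either end of the pair require variation-aware extension?

        True when an end has no seed chain at all, or its best chain's exact
        SNP-tolerant extension leaves at least ``min_unexplained_for_vara``
        read bases unexplained.
        """
        for read, hits in zip(read_pair, seed_hits):
            if not hits:
                return True
            groups: dict[tuple[str, int, str], list[int]] = {}
            for h in hits:
                groups.setdefault((h.chrom, h.pos - h.read_off, h.strand), []).append(h.read_off)
            best_un = None
            by_diag: dict[tuple[str, int, str], list[tuple[int, int]]] = {}
            for (chrom, diag, strand), offs in groups.items():
                s = read if strand == "+" else revcomp(read)
                bits = encode_read(s)
                for ra, rb in self._runs(offs, self.cfg.k):
                    p = diag + ra
                    if p < 0 or p + (rb - ra) > self.ref.length(chrom):
                        continue
                    a, b, _ = self._exact_extend(bits, chrom, ra, rb, p)
                    by_diag.setdefault((chrom, diag, strand), []).append((a, b))
            for cov in by_diag.values():
                cov.sort()
                un = len(read)
                end = 0
                for ca, cb in cov:
                    un -= max(0, min(cb, len(read)) - max(ca, end))
                    end = max(end, cb)
                best_un = un if best_un is None else min(best_un, un)
            if best_un is None or best_un >= self.cfg.min_unexplained_for_vara:
                return True
        return False

    def extend_with_vara(self, seed: SeedHit, read: str):
        """Variation-aware extension of both sides of one seed hit.

        Returns reference-coordinate :class:`Candidate` objects (the seed's
        exact block spliced with the VARA result of each side).
        """
        s = read if seed.strand == "+" else revcomp(read)
        bits = encode_read(s)
        c = self._extend_cluster(
            seed.chrom, seed.strand, [(seed.pos - seed.read_off, [seed.read_off])], s, bits
        )
        return [c] if c is not None else []

    # ------------------------------------------------------------ pairing

    def _rescue(self, anchors: list[Candidate], mate: str) -> list[Candidate]:
        out = []
        for a in anchors[:2]:
            hit = SeedHit(0, a.chrom, a.pos, self.cfg.k, a.strand)
            for w in anchor_mate([hit], self.cfg.insert, len(mate), self.ref.length(a.chrom)):
                out.extend(self.align_end(mate, (w.chrom, w.start, w.end)))
        if out:
            self.stats.rescued_ends += 1
        out.sort(key=lambda c: (c.score, c.e, c.pos))
        return out[:4]

    def _pair_score(self, a: Candidate, b: Candidate):
        proper = False
        if a.chrom == b.chrom and a.strand != b.strand:
            fwd, rev = (a, b) if a.strand == "+" else (b, a)
            span = rev.ref_end - fwd.pos
            im = self.cfg.insert
            if fwd.pos <= rev.pos and abs(span - im.mean) <= im.w * im.sd:
                proper = True
        return a.score + b.score, proper

    def map_pair(self, name: str, seq1: str, qual1: str, seq2: str, qual2: str):
        """Align one pair; returns two SAM record dicts."""
        self.stats.pairs += 1
        c1 = self.align_end(seq1)
        c2 = self.align_end(seq2)
        if c1:
            self.stats.seeded_ends += 1
        if c2:
            self.stats.seeded_ends += 1
        if c1 and not c2:
            c2 = self._rescue(c1, seq2)
        elif c2 and not c1:
            c1 = self._rescue(c2, seq1)

        best = None  # (score, a, b, proper)
        second_score = None
        if c1 and c2:
            scored = []
            for a in c1[:6]:
                for b in c2[:6]:
                    score, proper = self._pair_score(a, b)
                    scored.append((not proper, score, a.pos, b.pos, a, b, proper))
            scored.sort(key=lambda t: t[:4])
            best = scored[0]
            for t in scored[1:]:
                if (t[4].pos, t[5].pos) != (best[4].pos, best[5].pos):
                    second_score = t[1] + (1000 if t[0] and not best[0] else 0)
                    break
            a, b, proper = best[4], best[5], best[6]
            mapq = self._mapq(best[1], second_score)
            r1 = self._record(name, seq1, qual1, a, True, b, proper, mapq)
            r2 = self._record(name, seq2, qual2, b, False, a, proper, mapq)
        elif c1:
            mapq = self._mapq(c1[0].score, c1[1].score if len(c1) > 1 else None)
            r1 = self._record(name, seq1, qual1, c1[0], True, None, False, mapq)
            r2 = self._unmapped(name, seq2, qual2, False, c1[0])
        elif c2:
            mapq = self._mapq(c2[0].score, c2[1].score if len(c2) > 1 else None)
            r1 = self._unmapped(name, seq1, qual1, True, c2[0])
            r2 = self._record(name, seq2, qual2, c2[0], False, None, False, mapq)
        else:
            r1 = self._unmapped(name, seq1, qual1, True, None)
            r2 = self._unmapped(name, seq2, qual2, False, None)
        for r in (r1, r2):
            if r["flag"] & 4:
                self.stats.unmapped_ends += 1
            elif "S" in r["cigar"]:
                self.stats.softclip_records += 1
        return r1, r2

    def _mapq(self, s1, s2):
        if s2 is None:
            return self.cfg.mapq_cap
        if s2 <= s1:
            return 0
        return min(self.cfg.mapq_cap, int(40 * (s2 - s1) / max(1, s2)))

    def _record(self, name, seq, qual, c: Candidate, is_read1, mate: Candidate | None,
                proper, mapq):
        flag = 1 | (64 if is_read1 else 128)
        if proper:
            flag |= 2
        if c.strand == "-":
            flag |= 16
            seq, qual = revcomp(seq), qual[::-1]
        tlen = 0
        rnext, pnext = "*", -1
        if mate is not None:
            if mate.strand == "-":
                flag |= 32
            rnext = "=" if mate.chrom == c.chrom else mate.chrom
            pnext = mate.pos
            if mate.chrom == c.chrom:
                lo = min(c.pos, mate.pos)
                hi = max(c.ref_end, mate.ref_end)
                tlen = hi - lo if c.pos <= mate.pos else lo - hi
                if c.pos == mate.pos:
                    tlen = hi - lo if is_read1 else lo - hi
        else:
            flag |= 8
            rnext, pnext = "=", c.pos
        return {
            "qname": name,
            "flag": flag,
            "rname": c.chrom,
            "pos": c.pos,
            "mapq": mapq,
            "cigar": str(c.cigar),
            "rnext": rnext,
            "pnext": pnext,
            "tlen": tlen,
            "seq": seq,
            "qual": qual,
            "nm": c.nm,
            "as": -c.score,
        }

    def _unmapped(self, name, seq, qual, is_read1, mate: Candidate | None):
        flag = 1 | 4 | (64 if is_read1 else 128)
        rname, pos, rnext, pnext = "*", -1, "*", -1
        if mate is not None:
            if mate.strand == "-":
                flag |= 32
            rname, pos = mate.chrom, mate.pos  # placed with its mate
            rnext, pnext = "=", mate.pos
        else:
            flag |= 8
        return {
            "qname": name,
            "flag": flag,
            "rname": rname,
            "pos": pos,
            "mapq": 0,
            "cigar": "*",
            "rnext": rnext,
            "pnext": pnext,
            "tlen": 0,
            "seq": seq,
            "qual": qual,
            "nm": None,
            "as": None,
        }


def sam_header(ref: VarAwareReference, command_line: str = "varatree") -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": l} for n, l in ref.lengths.items()],
        "PG": [{"ID": "varatree", "PN": "varatree", "CL": command_line}],
    }


def write_sam(records, ref: VarAwareReference, out_path, command_line="varatree") -> None:
    """Write an iterable of record dicts to a SAM v1 file."""
    import pysam

    header = pysam.AlignmentHeader.from_dict(sam_header(ref, command_line))
    tid = {n: i for i, n in enumerate(ref.names)}
    with pysam.AlignmentFile(str(out_path), "w", header=header) as out:
        for r in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r["qname"]
            seg.flag = r["flag"]
            seg.reference_id = tid.get(r["rname"], -1)
            seg.reference_start = r["pos"]
            seg.mapping_quality = r["mapq"]
            if r["cigar"] != "*":
                seg.cigarstring = r["cigar"]
            if r["rnext"] == "=":
                seg.next_reference_id = seg.reference_id
            elif r["rnext"] != "*":
                seg.next_reference_id = tid[r["rnext"]]
            seg.next_reference_start = r["pnext"]
            seg.template_length = r["tlen"]
            seg.query_sequence = r["seq"]
            seg.query_qualities = pysam.qualitystring_to_array(r["qual"])
            tags = []
            if r["nm"] is not None:
                tags = [("NM", r["nm"]), ("AS", r["as"])]
            seg.set_tags(tags)
            out.write(seg)


def map_paired_end(
    ref: VarAwareReference,
    altseq: AltSeqIndex,
    fq1,
    fq2,
    out_sam,
    cfg: MapperConfig | None = None,
    seed_index: SeedIndex | None = None,
) -> MapStats:
    """Map a FASTQ pair to SAM; returns per-stage counters."""
    import pysam

    mapper = PairMapper(ref, altseq, cfg, seed_index=seed_index)

    def records():
        with pysam.FastxFile(str(fq1)) as f1, pysam.FastxFile(str(fq2)) as f2:
            for e1, e2 in zip(f1, f2):
                name = e1.name.removesuffix("/1")
                q1 = e1.quality or "I" * len(e1.sequence)
                q2 = e2.quality or "I" * len(e2.sequence)
                yield from mapper.map_pair(name, e1.sequence.upper(), q1, e2.sequence.upper(), q2)

    write_sam(records(), ref, out_sam)
    logger.info("mapping done: %s", mapper.stats.as_dict())
    return mapper.stats
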