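"""Variation-aware reference: 4-bit per-site allele codes plus an INDEL index.

SNPs are folded directly into the reference: every position carries a 4-bit
mask with one bit per nucleotide, the reference base's bit always set and one
extra bit per recorded SNP alternate.  A read base then matches a site in a
single AND — this is what makes known SNPs free during extension.  INDELs do
not fit a per-site code; they live in a separate position-sorted, interval-
queryable side index (one record per alternate allele).

Coordinates are 0-based half-open everywhere inside the package; VCF input is
converted once on the way in, SAM output converts back on the way out.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

from .errors import (
    DuplicateSequenceError,
    EmptyReferenceError,
    InvalidVariantError,
    UnknownChromosomeError,
)

logger = logging.getLogger(__name__)

# one bit per base; read N (or any other letter) encodes to 0 and matches nothing
BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
BIT_BASES = {1: "A", 2: "C", 4: "G", 8: "T"}
MASK_ALL = 0b1111

_READ_ENC = np.zeros(256, dtype=np.uint8)
_REF_ENC = np.full(256, MASK_ALL, dtype=np.uint8)  # non-ACGT reference -> all four bits
for _b, _v in BASE_BITS.items():
    _READ_ENC[ord(_b)] = _v
    _READ_ENC[ord(_b.lower())] = _v
    _REF_ENC[ord(_b)] = _v
    _REF_ENC[ord(_b.lower())] = _v


def encode_read(seq: str | bytes) -> np.ndarray:
    """Encode a read as per-base bit values (A=1,C=2,G=4,T=8, other=0)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _READ_ENC[np.frombuffer(seq, dtype=np.uint8)]


def encode_reference_masks(seq: str | bytes) -> np.ndarray:
    """Per-site 4-bit masks for a reference sequence (non-ACGT -> all bits)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _REF_ENC[np.frombuffer(seq, dtype=np.uint8)]


_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.encode().translate(_COMP)[::-1].decode()


class VType(str, Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True)
class VariantRecord:
    """A normalized, anchorless variant.

    ``pos`` is the 0-based coordinate of the first affected reference base;
    for an insertion it is the base *before which* ``alt_allele`` is inserted
    (``ref_allele`` is empty).  For a deletion ``alt_allele`` is empty and
    ``ref_allele`` spells the deleted bases.
    """

    chrom: str
    pos: int
    vtype: VType
    ref_allele: str
    alt_allele: str
    length: int
    id: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise InvalidVariantError(f"negative position: {self}")
        if self.vtype is VType.SNP:
            ok = (
                len(self.ref_allele) == len(self.alt_allele) == 1
                and self.ref_allele != self.alt_allele
                and self.length == 1
            )
        elif self.vtype is VType.INS:
            ok = self.length == len(self.alt_allele) - len(self.ref_allele) > 0
        else:
            ok = self.length == len(self.ref_allele) - len(self.alt_allele) > 0
        if not ok:
            raise InvalidVariantError(f"inconsistent alleles/length: {self}")

    @property
    def ref_span(self) -> tuple[int, int]:
        """Half-open reference interval affected (empty for insertions)."""
        return self.pos, self.pos + len(self.ref_allele)


class SiteCode(NamedTuple):
    """4-bit allele mask plus the original reference base at one site."""

    mask: int
    ref_base: str

    @property
    def alleles(self) -> frozenset:
        return frozenset(b for v, b in BIT_BASES.items() if self.mask & v)

    @property
    def has_snp(self) -> bool:
        return bin(self.mask).count("1") > 1


@dataclass
class _Chrom:
    masks: np.ndarray  # uint8 4-bit codes
    seq: str  # uppercased original reference


@dataclass
class VarAwareReference:
    """Per-chromosome 4-bit site codes; decoding always reproduces the input."""

    chroms: dict[str, _Chrom] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(c.seq) for n, c in self.chroms.items()}

    def _chrom(self, name: str) -> _Chrom:
        try:
            return self.chroms[name]
        except KeyError:
            raise UnknownChromosomeError(name) from None

    def length(self, chrom: str) -> int:
        return len(self._chrom(chrom).seq)

    def site(self, chrom: str, pos: int) -> SiteCode:
        c = self._chrom(chrom)
        return SiteCode(int(c.masks[pos]), c.seq[pos])

    def decode(self, chrom: str, start: int = 0, end: int | None = None) -> str:
        """Reference bases (uppercased input) over ``[start, end)``."""
        return self._chrom(chrom).seq[start:end]

    def codes(self, chrom: str, start: int = 0, end: int | None = None):
        """(mask array view, sequence slice) over ``[start, end)``."""
        c = self._chrom(chrom)
        return c.masks[start:end], c.seq[start:end]

    def copy(self) -> "VarAwareReference":
        return VarAwareReference(
            {n: _Chrom(c.masks.copy(), c.seq) for n, c in self.chroms.items()}
        )


def load_reference(fasta_source) -> VarAwareReference:
    """Build a SNP-free variation-aware reference from FASTA.

    Accepts a path or an open text handle.  Sequences are uppercased; non-ACGT
    bases keep their letter but receive an all-bits mask (they are excluded
    from seeding and never matched by a read ``N``).
    """
    if isinstance(fasta_source, (str, bytes)) or hasattr(fasta_source, "__fspath__"):
        handle: io.TextIOBase | None = open(fasta_source)
        close = True
    else:
        handle, close = fasta_source, False
    ref = VarAwareReference()
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in ref.chroms:
                raise DuplicateSequenceError(rec.id)
            seq = str(rec.seq).upper()
            ref.chroms[rec.id] = _Chrom(encode_reference_masks(seq), seq)
    finally:
        if close:
            handle.close()
    if not ref.chroms:
        raise EmptyReferenceError("no sequences in FASTA input")
    return ref


class AltSeqIndex:
    """Position-sorted, interval-queryable store of INDEL records.

    Insertions occupy the zero-length point ``pos`` and are reported for a
    window ``[s, e)`` iff ``s <= pos < e``; deletions overlap by their deleted
    span.  Results are sorted by position, ties by record id.
    """

    def __init__(self, known_chroms: Iterable[str] = ()):  # noqa: D107
        self._trees: dict[str, IntervalTree] = {}
        self._records: dict[str, list[VariantRecord]] = {}
        self.known_chroms: set[str] = set(known_chroms)
        self.n_rejected = 0

    def add(self, rec: VariantRecord) -> None:
        if rec.vtype is VType.SNP:
            raise InvalidVariantError("SNPs belong in site codes, not the INDEL index")
        s, e = rec.ref_span
        self._trees.setdefault(rec.chrom, IntervalTree()).addi(s, max(e, s + 1), rec)
        self._records.setdefault(rec.chrom, []).append(rec)
        self.known_chroms.add(rec.chrom)

    def query(self, chrom: str, start: int, end: int) -> list[VariantRecord]:
        if chrom not in self.known_chroms:
            raise UnknownChromosomeError(chrom)
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        out = [iv.data for iv in tree.overlap(start, end)]
        # insertion point semantics: keep INS only when start <= pos < end
        out = [
            r
            for r in out
            if (r.vtype is not VType.INS) or (start <= r.pos < end)
        ]
        out.sort(key=lambda r: (r.pos, r.id))
        return out

    def records(self, chrom: str | None = None) -> list[VariantRecord]:
        if chrom is not None:
            return sorted(self._records.get(chrom, []), key=lambda r: (r.pos, r.id))
        return sorted(
            (r for rs in self._records.values() for r in rs),
            key=lambda r: (r.chrom, r.pos, r.id),
        )

    def __len__(self) -> int:
        return sum(len(v) for v in self._records.values())


def variants_in_window(idx: AltSeqIndex, chrom: str, start: int, end: int) -> list[VariantRecord]:
    """All INDELs overlapping ``[start, end)``, deterministically ordered."""
    if not 0 <= start < end:
        raise ValueError(f"bad window [{start}, {end})")
    return idx.query(chrom, start, end)


def base_match(read_base: str, code: SiteCode) -> bool:
    """SNP-tolerant single-base match: true iff the read base's bit is set."""
    return bool(int(_READ_ENC[ord(read_base)]) & code.mask)


def integrate_variants(
    ref: VarAwareReference, variants: Iterable[VariantRecord]
) -> tuple[VarAwareReference, AltSeqIndex]:
    """Fold SNPs into the site codes and route INDELs to the side index.

    Records whose ``ref_allele`` does not match the reference at ``pos`` are
    rejected individually (counted and logged); the reference base of a site
    code is never changed, only its mask widens.
    """
    out = ref.copy()
    idx = AltSeqIndex(known_chroms=out.names)
    rejected = 0
    for v in variants:
        try:
            chrom = out._chrom(v.chrom)
        except UnknownChromosomeError:
            rejected += 1
            continue
        s, e = v.ref_span
        if e > len(chrom.seq) or chrom.seq[s:e] != v.ref_allele.upper():
            rejected += 1
            continue
        if v.vtype is VType.SNP:
            chrom.masks[v.pos] |= BASE_BITS.get(v.alt_allele.upper(), 0)
        else:
            idx.add(v)
    if rejected:
        logger.warning("integrate_variants: rejected %d record(s) (REF mismatch)", rejected)
    idx.n_rejected = rejected
    return out, idx


def read_vcf(path, default_chrom_order: Iterable[str] = ()) -> list[VariantRecord]:
    """Read VCF 4.x into normalized :class:`VariantRecord` objects.

    Multi-allelic lines are split per alternate allele; genotype columns are
    ignored.  VCF-style anchored alleles (shared leading base) are converted
    to anchorless insertions/deletions; symbolic or non-ACGT alleles and
    complex substitutions are skipped with a log message.
    """
    import pysam

    records: list[VariantRecord] = []
    skipped = 0
    next_id = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                v = _normalize_pair(rec.chrom, rec.pos - 1, ref, alt, next_id)
                if v is None:
                    skipped += 1
                    continue
                records.append(v)
                next_id += 1
    if skipped:
        logger.warning("read_vcf: skipped %d unsupported allele(s)", skipped)
    return records


def _normalize_pair(chrom: str, pos: int, ref: str, alt: str, vid: int) -> VariantRecord | None:
    if not ref or not alt:
        return None
    if any(c not in "ACGT" for c in ref + alt):
        return None
    # strip shared prefix (VCF anchor bases), then shared suffix
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    r, a = ref[p:], alt[p:]
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    pos += p
    if len(r) == 1 and len(a) == 1:
        return VariantRecord(chrom, pos, VType.SNP, r, a, 1, vid)
    if not r and a:
        return VariantRecord(chrom, pos, VType.INS, "", a, len(a), vid)
    if r and not a:
        return VariantRecord(chrom, pos, VType.DEL, r, "", len(r), vid)
    return None  # complex substitution: out of scope
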