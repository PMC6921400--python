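"""Synthetic data generation and alignment evaluation.

The generator emulates the variant-incorporated-genome study design at desk
scale: a uniform random genome, a planted non-overlapping variant set at
configurable SNP/INDEL rates with geometric INDEL lengths, and Illumina-like
FR read pairs simulated from the *variant-applied* genome (so variant-
spanning reads are the stress case) with i.i.d. base errors and an insert
size of 500 +/- 25 bp.  Truth positions are lifted back to original
reference coordinates, which is what mapping accuracy is scored against.

All generators are deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path as FsPath

import numpy as np

from .refvar import VariantRecord, VType, revcomp

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults are the scaled-down simulation design: a 200 kb single-
    chromosome genome, SNPs at 1e-3 per bp, insertions and deletions at
    1e-4 per bp each with geometric lengths capped at 20, and 100 bp read
    pairs at 0.2% base error with insert size 500 +/- 25.
    """

    genome_length: int = 200_000
    n_chroms: int = 1
    snp_rate: float = 1e-3
    ins_rate: float = 1e-4
    del_rate: float = 1e-4
    indel_geom_p: float = 0.3
    indel_max_len: int = 20
    read_length: int = 100
    n_pairs: int = 20_000
    insert_mean: float = 500.0
    insert_sd: float = 25.0
    error_rate: float = 0.002
    base_quality: int = 35
    seed: int = 1

    def __post_init__(self):
        for r in (self.snp_rate, self.ins_rate, self.del_rate, self.error_rate):
            if not 0 <= r < 1:
                raise ValueError(f"rate out of [0,1): {r}")
        if self.genome_length <= 0 or self.read_length <= 0 or self.n_pairs < 0:
            raise ValueError("sizes must be positive")
        if not 1 <= self.indel_max_len <= 50:
            raise ValueError("indel_max_len must be in [1, 50]")


def mhc_like_config(seed: int = 1, **kw) -> tuple[SimConfig, tuple[int, int, float]]:
    """A dense-variation preset: 5 kb sub-region at 10x variant density.

    Returns the config and the ``(start, end, multiplier)`` dense region on
    chromosome 0, to pass to :func:`simulate_variants`.
    """
    cfg = SimConfig(seed=seed, **kw)
    mid = cfg.genome_length // (2 * cfg.n_chroms)
    return cfg, (mid, mid + 5_000, 10.0)


def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Uniform random ACGT genome split over ``n_chroms`` chromosomes."""
    rng = rng or np.random.default_rng(cfg.seed)
    per = cfg.genome_length // cfg.n_chroms
    genome = {}
    for i in range(cfg.n_chroms):
        L = per if i < cfg.n_chroms - 1 else cfg.genome_length - per * (cfg.n_chroms - 1)
        genome[f"chr{i + 1}"] = _BASES[rng.integers(0, 4, L)].tobytes().decode()
    return genome


def simulate_variants(
    genome: dict[str, str],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    dense_region: tuple[int, int, float] | None = None,
) -> list[VariantRecord]:
    """Plant non-overlapping SNPs and INDELs at the configured rates.

    ``dense_region`` multiplies all rates inside ``[start, end)`` of the
    first chromosome.  INDEL lengths are geometric with success probability
    ``indel_geom_p``, truncated at ``indel_max_len``.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    out: list[VariantRecord] = []
    vid = 0
    for ci, (chrom, seq) in enumerate(genome.items()):
        L = len(seq)
        proposals: list[tuple[int, str, int]] = []  # (pos, kind, length)
        for kind, rate in (("SNP", cfg.snp_rate), ("INS", cfg.ins_rate), ("DEL", cfg.del_rate)):
            n = rng.poisson(rate * L)
            positions = rng.integers(1, max(2, L - cfg.indel_max_len - 1), n)
            for p in positions:
                length = 1
                if kind != "SNP":
                    length = int(min(rng.geometric(cfg.indel_geom_p), cfg.indel_max_len))
                proposals.append((int(p), kind, length))
        if dense_region is not None and ci == 0:
            s, e, mult = dense_region
            extra = {"SNP": cfg.snp_rate, "INS": cfg.ins_rate, "DEL": cfg.del_rate}
            for kind, rate in extra.items():
                n = rng.poisson(rate * (mult - 1) * max(0, e - s))
                positions = rng.integers(max(1, s), max(2, min(e, L - cfg.indel_max_len - 1)), n)
                for p in positions:
                    length = 1 if kind == "SNP" else int(
                        min(rng.geometric(cfg.indel_geom_p), cfg.indel_max_len)
                    )
                    proposals.append((int(p), kind, length))
        proposals.sort()
        last_end = -2
        for pos, kind, length in proposals:
            span = length if kind != "INS" else 0
            if pos <= last_end + 1 or pos + span >= L:
                continue  # keep planted variants separated by >= 1 ref base
            if kind == "SNP":
                ref_b = seq[pos]
                if ref_b not in "ACGT":
                    continue
                alt = "ACGT"[(("ACGT".index(ref_b)) + int(rng.integers(1, 4))) % 4]
                out.append(VariantRecord(chrom, pos, VType.SNP, ref_b, alt, 1, vid))
            elif kind == "INS":
                alt = _BASES[rng.integers(0, 4, length)].tobytes().decode()
                out.append(VariantRecord(chrom, pos, VType.INS, "", alt, length, vid))
            else:
                out.append(VariantRecord(chrom, pos, VType.DEL, seq[pos : pos + length], "", length, vid))
            vid += 1
            last_end = pos + span
    return out


@dataclass
class TruthRecord:
    """Original-reference truth for one simulated pair."""

    read_id: str
    chrom: str
    pos1: int  # 0-based leftmost aligned reference base, end 1
    strand1: str
    vids1: tuple[int, ...]
    pos2: int
    strand2: str
    vids2: tuple[int, ...]


@dataclass
class _AppliedChrom:
    hap: str
    hap2ref: np.ndarray  # ref position per hap base, -1 for inserted
    anchor: np.ndarray  # first real ref position at-or-after each hap base
    var_starts: np.ndarray  # variant footprints in hap coordinates
    var_ends: np.ndarray
    var_ids: np.ndarray
    var_is_junction: np.ndarray  # True for deletions (zero-width junction)


def apply_variants(seq: str, variants: list[VariantRecord]) -> _AppliedChrom:
    """Variant-applied haplotype plus the hap-to-reference coordinate map."""
    parts: list[str] = []
    maps: list[np.ndarray] = []
    vs_h: list[int] = []
    ve_h: list[int] = []
    vids: list[int] = []
    vjun: list[bool] = []
    cur = 0
    hap_len = 0

    def emit(s: str, m: np.ndarray):
        nonlocal hap_len
        parts.append(s)
        maps.append(m)
        hap_len += len(s)

    for v in sorted(variants, key=lambda v: (v.pos, v.id)):
        if v.pos > cur:
            emit(seq[cur : v.pos], np.arange(cur, v.pos, dtype=np.int64))
            cur = v.pos
        if v.vtype is VType.SNP:
            vs_h.append(hap_len)
            ve_h.append(hap_len + 1)
            vids.append(v.id)
            vjun.append(False)
            emit(v.alt_allele, np.array([v.pos], dtype=np.int64))
            cur = v.pos + 1
        elif v.vtype is VType.INS:
            vs_h.append(hap_len)
            ve_h.append(hap_len + v.length)
            vids.append(v.id)
            vjun.append(False)
            emit(v.alt_allele, np.full(v.length, -1, dtype=np.int64))
        else:
            vs_h.append(hap_len)
            ve_h.append(hap_len)
            vids.append(v.id)
            vjun.append(True)
            cur = v.pos + v.length
    if cur < len(seq):
        emit(seq[cur:], np.arange(cur, len(seq), dtype=np.int64))
    hap = "".join(parts)
    hap2ref = np.concatenate(maps) if maps else np.empty(0, np.int64)
    anchor = hap2ref.copy()
    nxt = len(seq)
    for i in range(len(anchor) - 1, -1, -1):
        if anchor[i] < 0:
            anchor[i] = nxt
        else:
            nxt = anchor[i]
    return _AppliedChrom(
        hap,
        hap2ref,
        anchor,
        np.asarray(vs_h, np.int64),
        np.asarray(ve_h, np.int64),
        np.asarray(vids, np.int64),
        np.asarray(vjun, bool),
    )


def _spanned(app: _AppliedChrom, s: int, e: int) -> tuple[int, ...]:
    jun = app.var_is_junction
    hit = np.where(
        (~jun & (app.var_starts < e) & (app.var_ends > s))
        | (jun & (app.var_starts > s) & (app.var_starts < e))
    )[0]
    return tuple(int(v) for v in app.var_ids[hit])


def simulate_reads(
    genome: dict[str, str],
    variants: list[VariantRecord],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str, str]], list[TruthRecord]]:
    """Draw FR pairs from the variant-applied genome.

    Returns ``(pairs, truth)`` where each pair is
    ``(read_id, seq1, seq2, qual)``: end 1 forward at the left of the
    fragment, end 2 reverse-complemented at the right.  Inserts larger than
    the chromosome are resampled.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    applied = {
        c: apply_variants(seq, [v for v in variants if v.chrom == c])
        for c, seq in genome.items()
    }
    names = list(genome)
    weights = np.array([len(applied[c].hap) for c in names], dtype=float)
    weights /= weights.sum()
    rl = cfg.read_length
    qual = chr(33 + cfg.base_quality) * rl
    pairs = []
    truth = []
    for i in range(cfg.n_pairs):
        chrom = names[int(rng.choice(len(names), p=weights))]
        app = applied[chrom]
        hlen = len(app.hap)
        for _ in range(1000):
            insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
            if rl <= insert <= hlen:
                break
        else:
            raise ValueError("chromosome shorter than any drawable insert")
        start = int(rng.integers(0, hlen - insert + 1))
        s1, e1 = start, start + rl
        s2, e2 = start + insert - rl, start + insert
        seq1 = app.hap[s1:e1]
        seq2 = revcomp(app.hap[s2:e2])
        seq1 = _add_errors(seq1, cfg.error_rate, rng)
        seq2 = _add_errors(seq2, cfg.error_rate, rng)
        rid = f"sim.{i}"
        pairs.append((rid, seq1, seq2, qual))
        truth.append(
            TruthRecord(
                rid,
                chrom,
                int(app.anchor[s1]),
                "+",
                _spanned(app, s1, e1),
                int(app.anchor[s2]),
                "-",
                _spanned(app, s2, e2),
            )
        )
    return pairs, truth


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = bytearray(seq.encode())
    for p in pos:
        cur = chr(s[p])
        choices = [b for b in "ACGT" if b != cur]
        s[p] = ord(choices[int(rng.integers(0, len(choices)))])
    return s.decode()


# ---------------------------------------------------------------- file I/O


def write_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_vcf(genome: dict[str, str], variants: list[VariantRecord], path) -> None:
    """VCF 4.2 with standard anchored INDEL representation."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varatree-simulate\n")
        for name, seq in genome.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.id)):
            seq = genome[v.chrom]
            if v.vtype is VType.SNP:
                pos1, ref, alt = v.pos + 1, v.ref_allele, v.alt_allele
            elif v.vtype is VType.INS:
                anchor = seq[v.pos - 1]
                pos1, ref, alt = v.pos, anchor, anchor + v.alt_allele
            else:
                anchor = seq[v.pos - 1]
                pos1, ref, alt = v.pos, anchor + v.ref_allele, anchor
            fh.write(f"{v.chrom}\t{pos1}\tv{v.id}\t{ref}\t{alt}\t.\tPASS\t.\n")


def write_fastq_pair(pairs, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, s1, s2, qual in pairs:
            f1.write(f"@{rid}/1\n{s1}\n+\n{qual[: len(s1)]}\n")
            f2.write(f"@{rid}/2\n{s2}\n+\n{qual[: len(s2)]}\n")


def write_truth(truth: list[TruthRecord], path) -> None:
    """Tab-separated truth table; positions are 0-based."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tpos1\tstrand1\tvids1\tpos2\tstrand2\tvids2\n")
        for t in truth:
            v1 = ",".join(map(str, t.vids1)) or "."
            v2 = ",".join(map(str, t.vids2)) or "."
            fh.write(
                f"{t.read_id}\t{t.chrom}\t{t.pos1}\t{t.strand1}\t{v1}"
                f"\t{t.pos2}\t{t.strand2}\t{v2}\n"
            )


def load_truth(path) -> dict[str, TruthRecord]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("read_id")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            parse = lambda s: tuple(int(x) for x in s.split(",")) if s != "." else ()
            out[f[0]] = TruthRecord(
                f[0], f[1], int(f[2]), f[3], parse(f[4]), int(f[5]), f[6], parse(f[7])
            )
    return out


def simulate_dataset(cfg: SimConfig, out_dir, dense_region=None):
    """Generate and write FASTA + VCF + FASTQ pair + truth TSV."""
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome = simulate_genome(cfg, rng)
    variants = simulate_variants(genome, cfg, rng, dense_region=dense_region)
    pairs, truth = simulate_reads(genome, variants, cfg, rng)
    write_fasta(genome, out / "genome.fa")
    write_vcf(genome, variants, out / "variants.vcf")
    write_fastq_pair(pairs, out / "reads_1.fq", out / "reads_2.fq")
    write_truth(truth, out / "truth.tsv")
    logger.info(
        "simulated %d pairs, %d variants over %d bp", len(pairs), len(variants), cfg.genome_length
    )
    return genome, variants, pairs, truth


# ---------------------------------------------------------------- evaluation


def evaluate_alignments(sam_path, truth: dict[str, TruthRecord], tolerance: int = 10) -> dict:
    """Score a SAM file against truth records.

    An end is accurate when its chromosome, strand and position (within
    ``tolerance`` bp) all match truth; unmapped ends count as inaccurate.
    Soft-clip counts are total records containing S and the subset of those
    whose end spans at least one planted variant.
    """
    import pysam

    n_ends = 0
    correct = 0
    unmapped = 0
    softclip = 0
    softclip_variant = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            qname = rec.query_name
            if qname not in truth:
                raise KeyError(f"read id {qname!r} missing from truth")
            t = truth[qname]
            n_ends += 1
            if rec.is_read2:
                tpos, tstrand, tvids = t.pos2, t.strand2, t.vids2
            else:
                tpos, tstrand, tvids = t.pos1, t.strand1, t.vids1
            if rec.is_unmapped:
                unmapped += 1
                continue
            if rec.cigarstring and "S" in rec.cigarstring:
                softclip += 1
                if tvids:
                    softclip_variant += 1
            strand = "-" if rec.is_reverse else "+"
            if (
                rec.reference_name == t.chrom
                and strand == tstrand
                and abs(rec.reference_start - tpos) <= tolerance
            ):
                correct += 1
    return {
        "n_ends": n_ends,
        "accuracy": 100.0 * correct / n_ends if n_ends else 0.0,
        "unmapped": unmapped,
        "softclip": softclip,
        "softclip_variant": softclip_variant,
    }
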