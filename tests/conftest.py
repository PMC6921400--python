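"""Shared fixtures: tiny reference builders and the scaled simulation runs."""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pytest

from varatree.mapper import MapperConfig, map_paired_end
from varatree.refvar import (
    VarAwareReference,
    VariantRecord,
    VType,
    integrate_variants,
    load_reference,
)
from varatree.simgen import (
    SimConfig,
    evaluate_alignments,
    simulate_genome,
    simulate_reads,
    simulate_variants,
    write_fastq_pair,
)
from varatree.vartree import RegionWindow, build_tree, enumerate_paths


def ref_from(seqs: dict[str, str]) -> VarAwareReference:
    fasta = "".join(f">{n}\n{s}\n" for n, s in seqs.items())
    return load_reference(io.StringIO(fasta))


def snp(chrom, pos, ref_b, alt, vid):
    return VariantRecord(chrom, pos, VType.SNP, ref_b, alt, 1, vid)


def ins(chrom, pos, alt, vid):
    return VariantRecord(chrom, pos, VType.INS, "", alt, len(alt), vid)


def dele(chrom, pos, ref_a, vid):
    return VariantRecord(chrom, pos, VType.DEL, ref_a, "", len(ref_a), vid)


def tree_of(seq: str, variants=(), chrom="c", start=0, ref=None, context=None):
    """Single-window tree over ``seq`` (optionally a slice of ``ref``)."""
    ref = ref or ref_from({chrom: seq})
    w = RegionWindow(chrom, start, start + len(seq))
    ctx = [context] if context is not None else None
    t = build_tree([(w, ref.codes(chrom, start, start + len(seq)))], variants=[list(variants)],
                   contexts=ctx)
    enumerate_paths(t)
    return t


@dataclass
class PipelineRun:
    metrics: dict
    stats: dict
    sam: str
    truth: dict


def _run_pipeline(tmp, cfg: SimConfig, use_variants=True, reuse=None):
    if reuse is None:
        rng = np.random.default_rng(cfg.seed)
        genome = simulate_genome(cfg, rng)
        variants = simulate_variants(genome, cfg, rng)
        pairs, truth = simulate_reads(genome, variants, cfg, rng)
        write_fastq_pair(pairs, tmp / "r1.fq", tmp / "r2.fq")
    else:
        genome, variants, truth = reuse
    ref = ref_from(genome)
    ref2, altseq = integrate_variants(ref, variants if use_variants else [])
    sam = str(tmp / ("out.sam" if use_variants else "out_novar.sam"))
    stats = map_paired_end(ref2, altseq, tmp / "r1.fq", tmp / "r2.fq", sam, MapperConfig())
    truth_by_id = {t.read_id: t for t in truth}
    metrics = evaluate_alignments(sam, truth_by_id, tolerance=10)
    return PipelineRun(metrics, stats.as_dict(), sam, truth_by_id), (genome, variants, truth)


@pytest.fixture(scope="session")
def sim_i100(tmp_path_factory):
    """Scaled Sim-i100 analogue: 200 kb, 20k pairs of 100 bp, 0.2% error."""
    tmp = tmp_path_factory.mktemp("i100")
    run, data = _run_pipeline(tmp, SimConfig(seed=1))
    run.data = data  # type: ignore[attr-defined]
    run.tmp = tmp  # type: ignore[attr-defined]
    return run


@pytest.fixture(scope="session")
def sim_i250(tmp_path_factory):
    """Scaled Sim-i250 analogue: same genome design, 10k pairs of 250 bp."""
    tmp = tmp_path_factory.mktemp("i250")
    run, _ = _run_pipeline(tmp, SimConfig(seed=1, read_length=250, n_pairs=10_000))
    return run


@pytest.fixture(scope="session")
def sim_i100_novar(sim_i100, tmp_path_factory):
    """The Sim-i100 reads remapped with all variant knowledge disabled."""
    run, _ = _run_pipeline(sim_i100.tmp, SimConfig(seed=1), use_variants=False,
                           reuse=sim_i100.data)
    return run


@pytest.fixture(scope="session")
def sim_zero_error(tmp_path_factory):
    """Sim-i100 design at zero sequencing error (variant effects isolated)."""
    tmp = tmp_path_factory.mktemp("zeroerr")
    run, _ = _run_pipeline(tmp, SimConfig(seed=1, error_rate=0.0))
    return run
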