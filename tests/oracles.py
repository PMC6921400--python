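"""Independent oracles used by the test suite.

These deliberately avoid the package's data structures: variant application
is plain string surgery, edit distance is a full O(n*m) dynamic program
(vectorized row-wise), and interval queries are linear scans.
"""

from __future__ import annotations

import numpy as np

BITS = {"A": 1, "C": 2, "G": 4, "T": 8}


def masks_of(seq: str, snps: dict[int, str] | None = None) -> np.ndarray:
    """4-bit site codes of a sequence with optional SNP alternates."""
    m = np.array([BITS.get(c, 15) for c in seq], dtype=np.uint8)
    for pos, alt in (snps or {}).items():
        m[pos] |= BITS[alt]
    return m


def read_bits(seq: str) -> np.ndarray:
    return np.array([BITS.get(c, 0) for c in seq], dtype=np.uint8)


def dp_edit(read: np.ndarray, hap: np.ndarray, semiglobal: bool = True) -> int:
    """Full-DP Levenshtein with SNP-tolerant zero-cost matches.

    Alignment is pinned at (0, 0).  ``semiglobal=True`` leaves the haplotype
    suffix free (read fully consumed); otherwise both ends are pinned.
    """
    n, m = len(read), len(hap)
    idx = np.arange(m + 1)
    prev = idx.astype(np.int64).copy()
    for i in range(1, n + 1):
        cost = ((hap & read[i - 1]) == 0).astype(np.int64)
        t = np.empty(m + 1, dtype=np.int64)
        t[0] = prev[0] + 1
        t[1:] = np.minimum(prev[1:] + 1, prev[:-1] + cost)
        prev = np.minimum.accumulate(t - idx) + idx
    return int(prev.min()) if semiglobal else int(prev[m])


def dp_edit_str(a: str, b: str) -> int:
    """Plain-character global Levenshtein distance."""
    n, m = len(a), len(b)
    A = np.frombuffer(a.encode(), np.uint8)
    B = np.frombuffer(b.encode(), np.uint8)
    idx = np.arange(m + 1)
    prev = idx.astype(np.int64).copy()
    for i in range(1, n + 1):
        cost = (B != A[i - 1]).astype(np.int64)
        t = np.empty(m + 1, dtype=np.int64)
        t[0] = prev[0] + 1
        t[1:] = np.minimum(prev[1:] + 1, prev[:-1] + cost)
        prev = np.minimum.accumulate(t - idx) + idx
    return int(prev[m])


def apply_subset(window_seq: str, wstart: int, subset) -> tuple[str, list[int]]:
    """Apply non-overlapping variants to a window by string surgery.

    Returns the realized haplotype and the per-base reference coordinate
    (-1 for inserted bases).  ``subset`` items need chrom-free fields
    (pos, vtype name, ref_allele, alt_allele, length).
    """
    out: list[str] = []
    coords: list[int] = []
    cur = 0
    wlen = len(window_seq)
    for v in sorted(subset, key=lambda v: (v.pos, getattr(v, "id", 0))):
        voff = v.pos - wstart
        name = v.vtype.value if hasattr(v.vtype, "value") else str(v.vtype)
        if name == "INS":
            seg = window_seq[cur:voff]
            out.append(seg)
            coords.extend(range(wstart + cur, wstart + voff))
            out.append(v.alt_allele)
            coords.extend([-1] * len(v.alt_allele))
            cur = voff
        elif name == "DEL":
            dstart = max(voff, 0)
            out.append(window_seq[cur:dstart])
            coords.extend(range(wstart + cur, wstart + dstart))
            cur = min(voff + v.length, wlen)
    out.append(window_seq[cur:])
    coords.extend(range(wstart + cur, wstart + wlen))
    return "".join(out), coords


def apply_subset_masks(masks: np.ndarray, wstart: int, subset) -> np.ndarray:
    """Site codes of the realized haplotype (inserted bases exact)."""
    out: list[int] = []
    cur = 0
    wlen = len(masks)
    for v in sorted(subset, key=lambda v: (v.pos, getattr(v, "id", 0))):
        voff = v.pos - wstart
        name = v.vtype.value if hasattr(v.vtype, "value") else str(v.vtype)
        if name == "INS":
            out.extend(int(x) for x in masks[cur:voff])
            out.extend(BITS[c] for c in v.alt_allele)
            cur = voff
        elif name == "DEL":
            dstart = max(voff, 0)
            out.extend(int(x) for x in masks[cur:dstart])
            cur = min(voff + v.length, wlen)
    out.extend(int(x) for x in masks[cur:])
    return np.array(out, dtype=np.uint8)


def linear_scan_window(records, chrom: str, start: int, end: int):
    """Brute-force interval query mirroring the half-open overlap contract."""
    out = []
    for r in records:
        if r.chrom != chrom:
            continue
        if r.vtype.value == "INS":
            if start <= r.pos < end:
                out.append(r)
        else:
            s, e = r.pos, r.pos + len(r.ref_allele)
            if e > start and s < end:
                out.append(r)
    return sorted(out, key=lambda r: (r.pos, r.id))


def correspondence(alt_ops, hap2ref, hap_start: int):
    """Read<->reference base correspondence implied by an ALT cigar.

    Walks the ops over an externally supplied haplotype-to-reference map,
    emits naive (M | I | D) events including reference bases skipped by
    taken deletions, then pairs adjacent I/D runs base-by-base into M.
    Returns a list of ("M", read_i, ref_j) / ("I", read_i) / ("D", ref_j).
    """
    ev = []
    hap, read_i = hap_start, 0
    last = None
    for ln, op in alt_ops:
        for _ in range(ln):
            if op == "S":
                read_i += 1
                continue
            if op == "I":
                ev.append(("I", read_i))
                read_i += 1
                continue
            j = hap2ref[hap]
            hap += 1
            if j >= 0 and last is not None and j > last + 1:
                ev.extend(("D", g) for g in range(last + 1, j))
            if j >= 0:
                last = j
            if op == "M":
                ev.append(("M", read_i, j) if j >= 0 else ("I", read_i))
                read_i += 1
            elif op == "D" and j >= 0:
                ev.append(("D", j))
    # pair adjacent insertion/deletion runs (restoration rules 2 and 4)
    out = []
    i = 0
    while i < len(ev):
        if ev[i][0] in "ID":
            run = [ev[i]]
            i += 1
            while i < len(ev) and ev[i][0] == run[0][0]:
                run.append(ev[i])
                i += 1
            if i < len(ev) and ev[i][0] in "ID" and ev[i][0] != run[0][0]:
                other = [ev[i]]
                i += 1
                while i < len(ev) and ev[i][0] == other[0][0]:
                    other.append(ev[i])
                    i += 1
                ins = run if run[0][0] == "I" else other
                dels = run if run[0][0] == "D" else other
                k = min(len(ins), len(dels))
                out.extend(("M", ins[j][1], dels[j][1]) for j in range(k))
                out.extend(ins[k:] if len(ins) > k else dels[k:])
            else:
                out.extend(run)
        else:
            out.append(ev[i])
            i += 1
    # drop unanchored edge deletions
    while out and out[0][0] == "D":
        out.pop(0)
    while out and out[-1][0] == "D":
        out.pop()
    return out
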