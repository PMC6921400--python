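"""Generalized Landau-Vishkin alignment over variation-tree paths (VARA).

The classical Landau-Vishkin algorithm iterates the edit distance ``e`` and,
for every diagonal ``d`` of the conceptual DP matrix, stores only the
farthest-reaching match.  Each round seeds a diagonal from its three
neighbours — ``L[e-1][d] + 1`` (substitution), ``L[e-1][d-1]`` (extra
haplotype base), ``L[e-1][d+1] + 1`` (extra read base) — and then slides
along exact matches, giving O(e * n) work instead of O(n^2).

Here the single sequence is replaced by the set of enumerated haplotype
paths of a variation tree: the matrix becomes three-dimensional — for every
``(e, d)`` a *set* of per-path farthest-reaching cells — and the innermost
exact-match slide is the SNP-tolerant traversal of the tree (indexed SNPs
and any taken INDEL edges cost zero edits; the INDEL edges are already part
of each path's realized haplotype, so a path's diagonal is measured in its
own haplotype frame and the variants' net reference displacement is
recovered from the path's coordinate map).  When several traversals reach
the same path id on one diagonal, only the longest extension survives to
the next round.  An alignment is emitted as soon as a path consumes the
entire read.

A heuristic prune drops paths carrying too many large variants —
by default more than 3 variants of >= 4 bp per 100 bp of read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cigar import CigarString
from .refvar import VariantRecord, encode_read
from .vartree import (
    DEFAULT_MAX_VARIANTS_PER_PATH,
    DEFAULT_PATH_CAP,
    Path,
    RegionWindow,
    VariationTree,
    enumerate_paths,
)
from .errors import PathExplosionError


def default_e_max(read_len: int) -> int:
    """Default edit budget: 6% of the read length, rounded up."""
    return math.ceil(0.06 * read_len)


@dataclass
class PruneConfig:
    """Edit budget and path-pruning knobs for :func:`vara_align`.

    ``e_max=None`` means "6% of the read length".  ``mode`` selects between
    extension alignment (read start pinned to the path start, path suffix
    free — the normal seed-extension case) and global alignment (both ends
    pinned, used when whole strings are compared).
    """

    e_max: int | None = None
    max_large_variants_per_100bp: int = 3
    large_variant_len: int = 4
    path_cap: int = DEFAULT_PATH_CAP
    max_variants_per_path: int = DEFAULT_MAX_VARIANTS_PER_PATH
    exhaustive: bool = False
    mode: str = "extension"  # or "global"

    def resolve_e_max(self, read_len: int) -> int:
        return self.e_max if self.e_max is not None else default_e_max(read_len)


@dataclass
class PathState:
    """Minimal per-path state consulted by the pruning heuristic."""

    e: int
    read_len: int
    taken: tuple[VariantRecord, ...] = ()


def prune_path(path_state: PathState, cfg: PruneConfig) -> bool:
    """True iff the path's traversal should be terminated.

    A path dies when its edit distance would exceed the budget or when it
    carries more than ``ceil(3 * read_len / 100)`` variants of length at
    least ``large_variant_len`` (the "3 per 100 bp" rate).
    """
    e_max = cfg.resolve_e_max(path_state.read_len)
    if path_state.e > e_max:
        return True
    allowance = math.ceil(
        cfg.max_large_variants_per_100bp * path_state.read_len / 100
    )
    n_large = sum(1 for v in path_state.taken if v.length >= cfg.large_variant_len)
    return n_large > allowance


def lv_edit_distance(a: str, b: str, e_max: int) -> int | None:
    """Classical Landau-Vishkin: least edit distance of two plain strings.

    Returns ``None`` when the distance exceeds ``e_max``.  O(e_max * n) cell
    updates; each cell stores the farthest reach on its diagonal.
    """
    n, m = len(a), len(b)
    if abs(m - n) > e_max:
        return None
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)

    def slide(r: int, d: int) -> int:
        lim = min(n - r, m - (r + d))
        if lim <= 0:
            return r
        eq = A[r : r + lim] == B[r + d : r + d + lim]
        return r + (lim if eq.all() else int(np.argmin(eq)))

    prev = {0: slide(0, 0)}
    if prev[0] >= n and m == n:
        return 0
    for e in range(1, e_max + 1):
        cur: dict[int, int] = {}
        for d in range(-e, e + 1):
            if d > m or -d > n:
                continue
            best = -1
            c = prev.get(d)
            if c is not None:
                best = c + 1
            c = prev.get(d - 1)
            if c is not None and c > best:
                best = c
            c = prev.get(d + 1)
            if c is not None and c + 1 > best:
                best = c + 1
            if best < 0:
                continue
            r = slide(min(best, n, m - d), d)
            cur[d] = r
            if d == m - n and r >= n:
                return e
        prev = cur
    return None


@dataclass
class CandidateAlignment:
    """A full-read extension of one path at edit distance ``e``.

    The CIGAR is in ALT coordinates (read vs the realized haplotype, M
    covering SNP-tolerant matches and mismatches); ``hap_start``/``hap_end``
    delimit the consumed haplotype span in forward path coordinates.
    """

    path_id: int
    e: int
    alt_cigar: CigarString
    window: RegionWindow
    hap_start: int
    hap_end: int
    variant_ids: tuple[int, ...]
    anchor: str = "left"
    d: int = 0
    read_consumed: int = 0


@dataclass
class LVState:
    """Bookkeeping mirrors of the 3-D matrix for inspection and tests."""

    L: dict[int, dict[int, set]] = field(default_factory=dict)  # e -> d -> {(pid, reach)}
    P_a_s: dict[int, set] = field(default_factory=dict)  # d -> path ids (last round)
    N_a_s: dict[int, dict[int, set]] = field(default_factory=dict)  # e -> d -> node ids
    Pk_a_s: dict[int, set] = field(default_factory=dict)  # e -> emitted path ids
    pset: set = field(default_factory=set)
    sets: list[str] = field(default_factory=list)


@dataclass
class VaraResult:
    """Alignments plus diagnostics from one :func:`vara_align` call."""

    alignments: list[CandidateAlignment]
    best_partial: CandidateAlignment | None
    pruned: bool
    cell_updates: int
    state: LVState

    def __iter__(self):
        return iter(self.alignments)

    def __len__(self):
        return len(self.alignments)

    def __getitem__(self, i):
        return self.alignments[i]


def select_longest(per_path_hits):
    """Keep, per (path id, diagonal), the hit with the longest extension.

    ``per_path_hits``: iterable of ``(path_id, ext_len)``,
    ``(path_id, ext_len, resume_cursor)`` or
    ``(path_id, ext_len, resume_cursor, d)`` tuples.  Ties prefer the
    smaller resume cursor, then the smaller path id.
    """
    best: dict[tuple[int, int], tuple] = {}
    for hit in per_path_hits:
        pid, ext = hit[0], hit[1]
        resume = hit[2] if len(hit) > 2 else None
        d = hit[3] if len(hit) > 3 else 0
        key = (pid, d)
        cur = best.get(key)
        if cur is None:
            best[key] = hit
            continue
        c_ext, c_resume = cur[1], cur[2] if len(cur) > 2 else None
        better = ext > c_ext or (
            ext == c_ext
            and resume is not None
            and c_resume is not None
            and resume < c_resume
        )
        if better:
            best[key] = hit
    return best


def _node_at(path: Path, hap_pos: int) -> int:
    for step in path.steps:
        if step.hap_start <= hap_pos < step.hap_end:
            return step.node_id
    return path.steps[-1].node_id if path.steps else -1


def vara_align(
    tree: VariationTree,
    read: str,
    cfg: PruneConfig | None = None,
    anchor: str = "left",
) -> VaraResult:
    """Align ``read`` against all live paths of ``tree``.

    ``anchor="left"`` pins the read's first base to the path start (right-of-
    seed extension); ``anchor="right"`` pins the last base to the path end
    (left-of-seed extension, run on reversed sequences internally).  Returns
    all candidate alignments at the least achievable edit distance (all
    levels when ``cfg.exhaustive``), plus the farthest partial extension for
    soft-clipping decisions.
    """
    cfg = cfg or PruneConfig()
    if not read:
        raise ValueError("empty read")
    n = len(read)
    e_max = cfg.resolve_e_max(n)

    pruned = False
    if not tree.paths:
        try:
            enumerate_paths(tree, cfg.max_variants_per_path, cfg.path_cap)
        except PathExplosionError:
            pruned = True
            mv = cfg.max_variants_per_path
            while mv > 0 and not tree.paths:
                mv -= 1
                try:
                    enumerate_paths(tree, mv, cfg.path_cap)
                except PathExplosionError:
                    continue
            if not tree.paths:
                enumerate_paths(tree, 0, max(cfg.path_cap, 1))

    rbits = encode_read(read)
    if anchor == "right":
        rbits = rbits[::-1]

    haps: dict[int, np.ndarray] = {}
    for p in tree.paths:
        if prune_path(PathState(e=0, read_len=n, taken=p.taken), cfg):
            pruned = True
            continue
        haps[p.id] = p.hap_masks[::-1] if anchor == "right" else p.hap_masks

    state = LVState()
    result = VaraResult([], None, pruned, 0, state)
    if not haps:
        return result

    def slide(pid: int, r: int, d: int) -> int:
        h = haps[pid]
        lim = min(n - r, len(h) - (r + d))
        if lim <= 0:
            return r
        ok = (h[r + d : r + d + lim] & rbits[r : r + lim]) != 0
        return r + (lim if ok.all() else int(np.argmin(ok)))

    # levels[e][(pid, d)] = (r0 post-op, r post-slide, op, prev_d)
    levels: list[dict[tuple[int, int], tuple[int, int, str, int]]] = []
    emitted: list[tuple[int, int, int]] = []  # (pid, d, e)
    best_partial_key: tuple[int, int, int] | None = None  # (reach, -e, ...) tracking
    cells = 0

    for e in range(e_max + 1):
        cur: dict[tuple[int, int], tuple[int, int, str, int]] = {}
        if e == 0:
            for pid in haps:
                cur[(pid, 0)] = (0, 0, "start", 0)
        else:
            prev = levels[e - 1]
            for (pid, d), (_, r, _, _) in prev.items():
                hlen = len(haps[pid])
                # substitution: consume one read and one haplotype base
                if r < n and r + d < hlen:
                    _propose(cur, pid, d, r + 1, "M", d)
                # extra read base (insertion in the read)
                if r < n:
                    _propose(cur, pid, d - 1, r + 1, "I", d)
                # extra haplotype base (deletion from the read)
                if r + d < hlen:
                    _propose(cur, pid, d + 1, r, "D", d)
        # slide every seeded cell along SNP-tolerant matches
        for (pid, d), (r0, _, op, pd) in list(cur.items()):
            r = slide(pid, r0, d)
            cur[(pid, d)] = (r0, r, op, pd)
            cells += 1
        levels.append(cur)

        # bookkeeping mirrors
        state.L[e] = {}
        state.P_a_s = {}
        for (pid, d), (_, r, _, _) in cur.items():
            state.L[e].setdefault(d, set()).add((pid, r))
            state.P_a_s.setdefault(d, set()).add(pid)
            state.pset.add(pid)
            if anchor == "left":
                state.N_a_s.setdefault(e, {}).setdefault(d, set()).add(
                    _node_at(tree.path(pid), min(r + d, len(haps[pid]) - 1))
                )
        state.sets.append(f"S_{e + 1}")

        for (pid, d), (_, r, _, _) in cur.items():
            if r >= n:
                if cfg.mode == "global" and r + d != len(haps[pid]):
                    continue
                emitted.append((pid, d, e))
                state.Pk_a_s.setdefault(e, set()).add(pid)
            key = (r, -e, -pid)
            if best_partial_key is None or key > best_partial_key:
                best_partial_key = key
                result.best_partial = _backtrace(tree, levels, pid, d, e, anchor, n)
        if emitted and not cfg.exhaustive:
            break

    result.cell_updates = cells
    out = [_backtrace(tree, levels, pid, d, e, anchor, n) for pid, d, e in emitted]
    out.sort(key=lambda c: (c.e, len(c.variant_ids), c.path_id, abs(c.d), c.d))
    result.alignments = out
    return result


def _propose(cur, pid, d, r0, op, prev_d) -> None:
    key = (pid, d)
    old = cur.get(key)
    if old is None or r0 > old[0]:
        cur[key] = (r0, r0, op, prev_d)


def _backtrace(
    tree: VariationTree, levels, pid: int, d: int, e: int, anchor: str, n: int
) -> CandidateAlignment:
    path = tree.path(pid)
    ops: list[tuple[int, str]] = []
    cur_d, cur_e = d, e
    final_r = levels[e][(pid, d)][1]
    while True:
        r0, r, op, prev_d = levels[cur_e][(pid, cur_d)]
        if r > r0:
            ops.append((r - r0, "M"))
        if op == "start":
            break
        ops.append((1, "M" if op == "M" else op))
        cur_d, cur_e = prev_d, cur_e - 1
    ops.reverse()
    hap_consumed = final_r + d
    hlen = len(path.hap_seq)
    if anchor == "right":
        ops.reverse()
        hap_start, hap_end = hlen - hap_consumed, hlen
    else:
        hap_start, hap_end = 0, hap_consumed
    return CandidateAlignment(
        path_id=pid,
        e=e,
        alt_cigar=CigarString(ops),
        window=path.window,
        hap_start=hap_start,
        hap_end=hap_end,
        variant_ids=path.variant_ids,
        anchor=anchor,
        d=d,
        read_consumed=final_r,
    )
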