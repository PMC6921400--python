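"""The variation tree: a per-seed pseudo-trie over local extension windows.

Extension windows collected around a candidate seed frequently share
fragments (repeats), so their site-code sequences are merged into a radix
trie whose nodes are maximal shared fragments, children ordered
alphabetically by leading reference base.  Regional INDELs attach to the
nodes covering their position; SNPs never branch the tree — they already
live inside the 4-bit site codes of the node labels.  A deletion may run
past the end of its window, in which case a *pseudo node* holding the
out-of-window reference bases is created so the deletion has a well-defined
end node.

Every choice of non-overlapping attached INDELs on one window realizes one
local haplotype; all such paths are enumerated up-front with deterministic
unique ids, de-duplicated on the realized sequence so no two paths spell the
same haplotype.  With a single window and no variants the tree degenerates
to one linear chain with a single path.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyWindowError, PathExplosionError, UnknownPathError
from .refvar import BASE_BITS, VariantRecord, VType

logger = logging.getLogger(__name__)

DEFAULT_MAX_VARIANTS_PER_PATH = 6
DEFAULT_PATH_CAP = 4096


@dataclass(frozen=True)
class RegionWindow:
    """A local reference window on one side of a seed (0-based half-open)."""

    chrom: str
    start: int
    end: int
    side: str = "R"  # "L" (left-of-seed) or "R" (right-of-seed)
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise EmptyWindowError(f"empty window {self.start}:{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


class TreeNode:
    """One maximal shared fragment of the window set."""

    __slots__ = (
        "id",
        "parent",
        "children",
        "label_masks",
        "label_seq",
        "attached",
        "is_pseudo",
        "window_ends",
    )

    def __init__(self, nid: int, parent: "TreeNode | None", masks: np.ndarray, seq: str,
                 is_pseudo: bool = False):
        self.id = nid
        self.parent = parent
        self.children: dict[tuple[str, int], TreeNode] = {}
        self.label_masks = masks
        self.label_seq = seq
        self.attached: list[tuple[int, VariantRecord]] = []  # (offset_in_node, record)
        self.is_pseudo = is_pseudo
        self.window_ends: list[int] = []  # indices of windows terminating here

    def sorted_children(self) -> list["TreeNode"]:
        return [self.children[k] for k in sorted(self.children)]


@dataclass(frozen=True)
class Step:
    """One element of a path: a node fragment or a variant edge."""

    kind: str  # "node" | "ins" | "del"
    hap_start: int
    hap_end: int
    node_id: int = -1
    variant: VariantRecord | None = None


@dataclass
class Path:
    """One enumerated haplotype over one window, with a unique id.

    ``ref_off[i]`` is the absolute reference coordinate of haplotype base
    ``i`` or ``-1`` if the base is inserted; together with ``steps`` this is
    the coordinate map used for traversal and CIGAR restoration.
    """

    id: int
    window_index: int
    window: RegionWindow
    variant_ids: tuple[int, ...]
    taken: tuple[VariantRecord, ...]
    hap_masks: np.ndarray
    hap_seq: str
    ref_off: np.ndarray
    steps: tuple[Step, ...]
    provenance: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hap_seq)


@dataclass
class VariationTree:
    root: TreeNode
    nodes: list[TreeNode]
    windows: list[tuple[RegionWindow, np.ndarray, str]]
    window_variants: list[list[VariantRecord]]
    contexts: list[tuple[np.ndarray, str] | None]
    chains: list[list[tuple[TreeNode, int, int]]]  # per window: (node, woff_start, woff_end)
    del_end_nodes: dict[tuple[int, int], int] = field(default_factory=dict)
    paths: list[Path] = field(default_factory=list)
    _path_by_id: dict[int, Path] = field(default_factory=dict)
    path_lookup: dict[tuple[int, frozenset], int] = field(default_factory=dict)

    def path(self, path_id: int) -> Path:
        try:
            return self._path_by_id[path_id]
        except KeyError:
            raise UnknownPathError(path_id) from None


def build_tree(
    windows,
    variants=None,
    contexts=None,
) -> VariationTree:
    """Build the pseudo-trie over ``windows`` and attach regional variants.

    Parameters
    ----------
    windows
        sequence of ``(RegionWindow, (masks, seq))`` pairs — the decoded
        site-code sequences of the extension windows (same side of one seed).
    variants
        per-window collections of INDEL :class:`VariantRecord`; variants not
        overlapping their window are dropped with a log message.
    contexts
        optional per-window ``(masks, seq)`` of reference bases immediately
        after the window, consulted when a deletion runs past the window end
        (pseudo-node creation).
    """
    windows = list(windows)
    if not windows:
        raise EmptyWindowError("no windows")
    norm: list[tuple[RegionWindow, np.ndarray, str]] = []
    for w, codes in windows:
        masks, seq = codes
        if len(seq) == 0:
            raise EmptyWindowError(f"window {w} has empty sequence")
        norm.append((w, np.asarray(masks, dtype=np.uint8), seq))
    nvars: list[list[VariantRecord]] = []
    for i, (w, _, _) in enumerate(norm):
        vs = list(variants[i]) if variants is not None and variants[i] else []
        kept = []
        for v in vs:
            s, e = v.ref_span
            # insertions at the window's right edge are kept: they sit on the
            # junction between a left-of-seed window and the seed itself
            inside = (w.start <= v.pos <= w.end) if v.vtype is VType.INS else (
                e > w.start and s < w.end
            )
            if inside:
                kept.append(v)
            else:
                logger.debug("variant id=%d outside window %s: dropped", v.id, w)
        kept.sort(key=lambda v: (v.pos, v.id))
        nvars.append(kept)
    raw_ctxs = list(contexts) if contexts is not None else [None] * len(norm)
    ctxs: list[tuple[np.ndarray, str] | None] = []
    for c in raw_ctxs:
        if c is None:
            ctxs.append(None)
        else:
            m, s = c
            ctxs.append((np.asarray(m, dtype=np.uint8), s))

    root = TreeNode(0, None, np.empty(0, np.uint8), "")
    nodes = [root]

    def insert(masks: np.ndarray, seq: str, wi: int) -> None:
        node, i = root, 0
        while True:
            if i == len(seq):
                node.window_ends.append(wi)
                return
            key = (seq[i], int(masks[i]))
            child = node.children.get(key)
            if child is None:
                child = TreeNode(len(nodes), node, masks[i:].copy(), seq[i:])
                nodes.append(child)
                node.children[key] = child
                child.window_ends.append(wi)
                return
            lab_m, lab_s = child.label_masks, child.label_seq
            lim = min(len(lab_s), len(seq) - i)
            eq = (lab_m[:lim] == masks[i : i + lim]) & (
                np.frombuffer(lab_s[:lim].encode(), np.uint8)
                == np.frombuffer(seq[i : i + lim].encode(), np.uint8)
            )
            l = int(np.argmin(eq)) if not eq.all() else lim
            if l < len(lab_s):
                # split the child at l
                mid = TreeNode(len(nodes), node, lab_m[:l].copy(), lab_s[:l])
                nodes.append(mid)
                node.children[key] = mid
                child.label_masks, child.label_seq = lab_m[l:].copy(), lab_s[l:]
                child.parent = mid
                mid.children[(child.label_seq[0], int(child.label_masks[0]))] = child
                child = mid
            node, i = child, i + l

    for wi, (_, masks, seq) in enumerate(norm):
        insert(masks, seq, wi)

    # recover per-window root-to-leaf chains (node, woff_start, woff_end)
    chains: list[list[tuple[TreeNode, int, int]]] = []
    for wi, (_, masks, seq) in enumerate(norm):
        chain = []
        node, i = root, 0
        while i < len(seq):
            node = node.children[(seq[i], int(masks[i]))]
            l = len(node.label_seq)
            chain.append((node, i, i + l))
            i += l
        chains.append(chain)

    tree = VariationTree(root, nodes, norm, nvars, ctxs, chains)

    # variant attachment: every chain node overlapping the variant's span
    for wi, vs in enumerate(nvars):
        w = norm[wi][0]
        wlen = len(norm[wi][2])
        for v in vs:
            voff = v.pos - w.start
            vend = voff + (v.length if v.vtype is VType.DEL else 0)
            attached_any = False
            for node, s, e in chains[wi]:
                covers = (s <= voff < e) or (v.vtype is VType.DEL and voff < e and vend > s)
                if covers and not any(rec.id == v.id for _, rec in node.attached):
                    node.attached.append((max(voff, s) - s, v))
                    attached_any = True
            if not attached_any and v.vtype is VType.INS and voff == wlen and chains[wi]:
                node, s, e = chains[wi][-1]  # junction insertion at the window end
                node.attached.append((e - s, v))
            if v.vtype is VType.DEL:
                if vend <= wlen:
                    for node, s, e in chains[wi]:
                        if s < vend <= e or (vend == 0 and s == 0):
                            tree.del_end_nodes[(wi, v.id)] = node.id
                            break
                else:
                    ctx = ctxs[wi]
                    over = vend - wlen
                    if ctx is not None and len(ctx[1]) >= over:
                        pm, ps = ctx[0][:over].copy(), ctx[1][:over]
                    else:
                        pm, ps = np.full(over, 0, np.uint8), "?" * over
                    leaf = chains[wi][-1][0] if chains[wi] else root
                    pseudo = TreeNode(len(nodes), leaf, pm, ps, is_pseudo=True)
                    nodes.append(pseudo)
                    tree.del_end_nodes[(wi, v.id)] = pseudo.id
    for node in nodes:
        node.attached.sort(key=lambda t: (t[0], t[1].id))
    return tree


def _conflicts(a: VariantRecord, b: VariantRecord) -> bool:
    if a.vtype is VType.INS and b.vtype is VType.INS:
        return a.pos == b.pos
    s1, e1 = a.ref_span
    s2, e2 = b.ref_span
    if a.vtype is VType.INS:
        return s2 < a.pos < e2
    if b.vtype is VType.INS:
        return s1 < b.pos < e1
    return e1 > s2 and e2 > s1


def _realize(
    tree: VariationTree, wi: int, taken: tuple[VariantRecord, ...]
):
    """Apply ``taken`` (sorted, non-conflicting) to window ``wi``.

    Returns (hap_masks, hap_seq, ref_off, steps).
    """
    w, masks, seq = tree.windows[wi]
    ctx = tree.contexts[wi]
    chain = tree.chains[wi]
    wlen = len(seq)
    hm: list[np.ndarray] = []
    hs: list[str] = []
    ro: list[np.ndarray] = []
    steps: list[Step] = []
    hap_len = 0

    def append_ref(a: int, b: int) -> None:
        """Append window ref segment [a, b), split at chain node boundaries."""
        nonlocal hap_len
        cur = a
        for node, s, e in chain:
            lo, hi = max(cur, s), min(b, e)
            if lo < hi:
                hm.append(masks[lo:hi])
                hs.append(seq[lo:hi])
                ro.append(np.arange(w.start + lo, w.start + hi, dtype=np.int64))
                steps.append(Step("node", hap_len, hap_len + hi - lo, node.id))
                hap_len += hi - lo
                cur = hi
            if cur >= b:
                break

    cur = 0
    for v in taken:
        voff = v.pos - w.start
        if v.vtype is VType.INS:
            if voff > cur:
                append_ref(cur, voff)
                cur = voff
            bits = np.array([BASE_BITS[c] for c in v.alt_allele], dtype=np.uint8)
            hm.append(bits)
            hs.append(v.alt_allele)
            ro.append(np.full(len(bits), -1, dtype=np.int64))
            steps.append(Step("ins", hap_len, hap_len + len(bits), -1, v))
            hap_len += len(bits)
        else:  # DEL
            dstart = max(voff, 0)
            if dstart > cur:
                append_ref(cur, dstart)
            steps.append(Step("del", hap_len, hap_len, tree.del_end_nodes.get((wi, v.id), -1), v))
            dend = voff + v.length
            if dend >= wlen:
                # deletion runs to/past the window end; continue in context if any
                over = dend - wlen
                if ctx is not None and over < len(ctx[1]):
                    cm, cs = ctx[0][over:], ctx[1][over:]
                    hm.append(cm)
                    hs.append(cs)
                    ro.append(np.arange(w.end + over, w.end + over + len(cs), dtype=np.int64))
                    steps.append(
                        Step("node", hap_len, hap_len + len(cs), tree.del_end_nodes.get((wi, v.id), -1))
                    )
                    hap_len += len(cs)
                cur = wlen
                break
            cur = dend
    if cur < wlen:
        append_ref(cur, wlen)
    if hm:
        hap_masks = np.concatenate(hm)
        ref_off = np.concatenate(ro)
    else:
        hap_masks = np.empty(0, np.uint8)
        ref_off = np.empty(0, np.int64)
    return hap_masks, "".join(hs), ref_off, tuple(steps)


def enumerate_paths(
    tree: VariationTree,
    max_variants_per_path: int = DEFAULT_MAX_VARIANTS_PER_PATH,
    path_cap: int = DEFAULT_PATH_CAP,
) -> list[Path]:
    """Enumerate all haplotype paths with deterministic unique ids.

    Per window, variant subsets are visited in (size, id-tuple) order —
    the variant-free path first, then single-variant paths by id, and so on —
    so ids are stable across runs.  Paths realizing an identical sequence are
    de-duplicated keeping the smallest id; all source windows remain in the
    survivor's provenance.
    """
    paths: list[Path] = []
    by_key: dict[tuple, Path] = {}
    next_id = 0
    total = 0
    for wi in range(len(tree.windows)):
        vs = tree.window_variants[wi]
        subsets: list[tuple[VariantRecord, ...]] = []
        for size in range(0, min(max_variants_per_path, len(vs)) + 1):
            for combo in itertools.combinations(vs, size):
                if any(_conflicts(a, b) for a, b in itertools.combinations(combo, 2)):
                    continue
                subsets.append(tuple(sorted(combo, key=lambda v: (v.pos, v.id))))
                total += 1
                if total > path_cap:
                    raise PathExplosionError(
                        f"candidate paths exceed cap {path_cap}; "
                        "lower max_variants_per_path or enable pruning"
                    )
        for combo in subsets:
            hap_masks, hap_seq, ref_off, steps = _realize(tree, wi, combo)
            vids = tuple(v.id for v in combo)
            key = (hap_seq, hap_masks.tobytes())
            prev = by_key.get(key)
            if prev is not None:
                if wi not in prev.provenance:
                    prev.provenance.append(wi)
                tree.path_lookup[(wi, frozenset(vids))] = prev.id
                continue
            p = Path(
                id=next_id,
                window_index=wi,
                window=tree.windows[wi][0],
                variant_ids=vids,
                taken=combo,
                hap_masks=hap_masks,
                hap_seq=hap_seq,
                ref_off=ref_off,
                steps=steps,
                provenance=[wi],
            )
            next_id += 1
            by_key[key] = p
            paths.append(p)
            tree.path_lookup[(wi, frozenset(vids))] = p.id
    tree.paths = paths
    tree._path_by_id = {p.id: p for p in paths}
    return paths


def path_sequence(tree: VariationTree, path_id: int):
    """Realized haplotype string and its coordinate map for one path."""
    p = tree.path(path_id)
    return p.hap_seq, p.ref_off


def dump_tree(tree: VariationTree) -> str:
    """Debug text dump: one node per line (id, parent, label, variants)."""
    lines = []
    for n in tree.nodes:
        vs = ";".join(f"{off}:{rec.vtype.value}{rec.id}" for off, rec in n.attached)
        parent = n.parent.id if n.parent is not None else "."
        flag = " pseudo" if n.is_pseudo else ""
        lines.append(f"{n.id}\t{parent}\t{n.label_seq or '.'}\t{vs or '.'}{flag}")
    return "\n".join(lines)
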