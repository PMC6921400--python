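"""Queue-driven breadth-first traversal of the variation tree (VATR).

The traversal extends an exact — but SNP-tolerant — match frontier along all
live haplotype paths simultaneously.  A single base "matches" a site when
its bit is set in the site's 4-bit code, so indexed SNPs never interrupt a
match run.  Three kinds of work enter the queue: the successor node of a
fully matched node, a newly reached variant edge, and the end node of a
deletion edge.  Insertion edges are matched exactly against the inserted
allele (inserted bases carry single-bit codes, so no SNP tolerance applies
inside them); deletion edges consume zero read bases and resume at their end
node.  An entry that mismatches, or runs out of read, leaves the queue and
is reported in the corresponding result bucket.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .refvar import encode_read
from .vartree import Path, VariationTree

# frontier entry kinds (the three enqueue categories)
SUCCESSOR_NODE = "successor-node"
NEW_VARIANT = "new-variant"
VARIANT_END_NODE = "variant-end-node"
_KINDS = frozenset({SUCCESSOR_NODE, NEW_VARIANT, VARIANT_END_NODE})


def _as_masks(label) -> np.ndarray:
    if isinstance(label, np.ndarray):
        return label
    if isinstance(label, (str, bytes)):
        from .refvar import encode_reference_masks

        return encode_reference_masks(label)
    return np.asarray([int(m) for m in label], dtype=np.uint8)


def match_run(read, read_off: int, node_label, node_off: int, limit: int | None = None) -> int:
    """Length of the maximal SNP-tolerant exact match run.

    ``read`` may be a string or a pre-encoded bit array; ``node_label`` a
    mask array, a list of masks, or a plain string (encoded as reference).
    """
    rbits = read if isinstance(read, np.ndarray) else encode_read(read)
    masks = _as_masks(node_label)
    n = min(len(rbits) - read_off, len(masks) - node_off)
    if limit is not None:
        n = min(n, limit)
    if n <= 0:
        return 0
    ok = (masks[node_off : node_off + n] & rbits[read_off : read_off + n]) != 0
    if ok.all():
        return n
    return int(np.argmin(ok))


@dataclass(frozen=True)
class FrontierEntry:
    """One unit of traversal work: resume path ``path_id`` at a step."""

    kind: str
    path_id: int
    step_idx: int = 0
    offset: int = 0  # genomic offset within the target step
    read_off: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown frontier kind {self.kind!r}")


@dataclass
class TraversalState:
    """Bookkeeping arrays of the breadth-first traversal."""

    P_a: list[int] = field(default_factory=list)  # path id per processed entry
    N_a: dict[int, list[int]] = field(default_factory=dict)  # path -> node chain
    Pk_a: list[int] = field(default_factory=list)  # candidate (read-exhausting) paths


@dataclass
class TraversalResult:
    """Where every frontier entry stopped, plus path-set bookkeeping.

    ``stops`` buckets: ``"mismatch"`` (read base failed the site code — also
    used for a mismatch inside an insertion allele), ``"hap_end"`` (the path
    ran out of sequence with read remaining) and ``"ran_to_end"`` (the read
    was exhausted).  Each item is ``(path_id, read_off, resume_cursor)`` with
    the resume cursor in haplotype coordinates.  ``events`` records variant
    edges traversed at zero cost as ``(op, path_id, hap_off, length)`` with
    op ``"I"``/``"D"`` — the diagonal displacement they contribute.
    """

    stops: dict[str, list[tuple[int, int, int]]]
    events: list[tuple[str, int, int, int]]
    state: TraversalState
    pset: set[int]
    sets: dict[str, str]


def initial_frontier(tree: VariationTree, read_off: int = 0) -> list[FrontierEntry]:
    """Frontier entries starting every enumerated path at its first step."""
    return [
        FrontierEntry(SUCCESSOR_NODE, p.id, 0, 0, read_off)
        for p in tree.paths
    ]


_set_counter = 0


def traverse_extend(tree: VariationTree, read, frontier) -> TraversalResult:
    """Process the frontier to exhaustion over the enumerated paths.

    Matching runs along each path's realized haplotype; node fragments use
    SNP-tolerant site codes, insertion alleles exact codes, deletion edges
    consume nothing and immediately enqueue their end node.  Every
    ``(path, step, offset, read offset)`` state is processed at most once.
    """
    global _set_counter
    rbits = read if isinstance(read, np.ndarray) else encode_read(read)
    n = len(rbits)
    queue: deque[FrontierEntry] = deque(frontier)
    seen: set[tuple[int, int, int, int]] = set()
    stops: dict[str, list[tuple[int, int, int]]] = {
        "mismatch": [],
        "hap_end": [],
        "ran_to_end": [],
    }
    events: list[tuple[str, int, int, int]] = []
    state = TraversalState()
    pset: set[int] = set()

    while queue:
        ent = queue.popleft()
        key = (ent.path_id, ent.step_idx, ent.offset, ent.read_off)
        if key in seen:
            continue
        seen.add(key)
        path: Path = tree.path(ent.path_id)
        pset.add(path.id)
        state.P_a.append(path.id)
        if ent.step_idx >= len(path.steps):
            bucket = "ran_to_end" if ent.read_off >= n else "hap_end"
            stops[bucket].append((path.id, ent.read_off, len(path.hap_seq)))
            if bucket == "ran_to_end":
                state.Pk_a.append(path.id)
            continue
        step = path.steps[ent.step_idx]
        if step.kind == "del":
            events.append(("D", path.id, step.hap_start, step.variant.length))
            queue.append(
                FrontierEntry(VARIANT_END_NODE, path.id, ent.step_idx + 1, 0, ent.read_off)
            )
            continue
        cur = step.hap_start + ent.offset
        if step.kind == "node":
            state.N_a.setdefault(path.id, []).append(step.node_id)
        run = match_run(rbits, ent.read_off, path.hap_masks, cur, limit=step.hap_end - cur)
        read_off = ent.read_off + run
        cur += run
        if read_off >= n:
            stops["ran_to_end"].append((path.id, read_off, cur))
            state.Pk_a.append(path.id)
            continue
        if cur < step.hap_end:
            stops["mismatch"].append((path.id, read_off, cur))
            continue
        if step.kind == "ins":
            events.append(("I", path.id, step.hap_start, step.variant.length))
        nxt = ent.step_idx + 1
        if nxt >= len(path.steps):
            stops["hap_end"].append((path.id, read_off, cur))
            continue
        nstep = path.steps[nxt]
        kind = NEW_VARIANT if nstep.kind in ("ins", "del") else (
            VARIANT_END_NODE if step.kind in ("ins", "del") else SUCCESSOR_NODE
        )
        queue.append(FrontierEntry(kind, path.id, nxt, 0, read_off))

    _set_counter += 1
    sets = {b: f"S_{_set_counter}_{b}" for b, items in stops.items() if items}
    return TraversalResult(stops=stops, events=events, state=state, pset=pset, sets=sets)
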