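"""CIGAR handling and restoration from haplotype to reference coordinates.

An extension alignment is first expressed against the variant-applied
haplotype of a path (the *ALT* CIGAR).  For SAM output it must be restored
to the original reference: the read-to-haplotype operations are composed
with the haplotype-to-reference map induced by the taken variants.  Four
situations fall out of the composition:

* an ALT deletion of an inserted base cancels (a 1 bp deletion inside a
  1 bp insertion variant restores to plain match/mismatch);
* an ALT insertion adjacent to a taken deletion is matched against the
  deleted reference bases (a 1 bp insertion inside a 1 bp deletion variant
  restores to match/mismatch);
* surviving matches against inserted bases restore to a reference
  insertion (deletion inside a longer insertion variant);
* an ALT insertion inside a longer deletion variant restores to a shorter
  reference deletion plus match/mismatch.

M is the SAM "match or mismatch" dialect throughout; SNP-tolerant matches
stay M.  Soft clips pass through composition unchanged.
"""

from __future__ import annotations

from typing import Iterable

from .errors import CigarCompositionError

_READ_OPS = frozenset("MIS")
_REF_OPS = frozenset("MD")
_OPS = frozenset("MIDS")


class CigarString:
    """An ordered list of ``(length, op)`` pairs, ops in {M, I, D, S}.

    Adjacent equal ops are merged and zero-length ops dropped on
    construction, so the run list is always canonical.
    """

    __slots__ = ("ops",)

    def __init__(self, ops: Iterable[tuple[int, str]] = ()):  # noqa: D107
        canon: list[tuple[int, str]] = []
        for length, op in ops:
            if op not in _OPS:
                raise ValueError(f"unsupported CIGAR op {op!r}")
            if length < 0:
                raise ValueError(f"negative CIGAR length {length}")
            if length == 0:
                continue
            if canon and canon[-1][1] == op:
                canon[-1] = (canon[-1][0] + length, op)
            else:
                canon.append((length, op))
        self.ops = canon

    @classmethod
    def parse(cls, text: str) -> "CigarString":
        ops = []
        num = ""
        for ch in text:
            if ch.isdigit():
                num += ch
            else:
                if not num:
                    raise ValueError(f"malformed CIGAR {text!r}")
                ops.append((int(num), ch))
                num = ""
        if num:
            raise ValueError(f"malformed CIGAR {text!r}")
        return cls(ops)

    def __str__(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.ops) or "*"

    def __repr__(self) -> str:
        return f"CigarString({self})"

    def __eq__(self, other) -> bool:
        if isinstance(other, str):
            return str(self) == other
        return isinstance(other, CigarString) and self.ops == other.ops

    def __add__(self, other: "CigarString") -> "CigarString":
        return CigarString(self.ops + other.ops)

    def __bool__(self) -> bool:
        return bool(self.ops)

    @property
    def read_len(self) -> int:
        return sum(n for n, op in self.ops if op in _READ_OPS)

    @property
    def ref_len(self) -> int:
        return sum(n for n, op in self.ops if op in _REF_OPS)

    @property
    def clipped(self) -> int:
        return sum(n for n, op in self.ops if op == "S")

    def edit_ops(self) -> int:
        """Count of I/D bases (mismatches inside M are not visible here)."""
        return sum(n for n, op in self.ops if op in "ID")


def validate_cigar(cigar, read_len: int, ref_span: int) -> bool:
    """Check consumption identities and run canonicalization."""
    if isinstance(cigar, str):
        try:
            cigar = CigarString.parse(cigar)
        except ValueError:
            return False
    for i, (n, _) in enumerate(cigar.ops):
        if n < 1:
            return False
        if i and cigar.ops[i][1] == cigar.ops[i - 1][1]:
            return False
    return cigar.read_len == read_len and cigar.ref_len == ref_span


def compose_ref_cigar(alt_cigar, path, window=None, hap_start: int = 0):
    """Restore an ALT-coordinate CIGAR to reference coordinates.

    ``alt_cigar`` aligns the read to ``path``'s realized haplotype starting
    at haplotype offset ``hap_start``.  Returns ``(ref_pos, CigarString)``
    with ``ref_pos`` the leftmost reference base consumed (0-based); when
    the alignment begins inside an insertion variant the position is the
    first reference base after the insertion anchor.
    """
    if isinstance(alt_cigar, str):
        alt_cigar = CigarString.parse(alt_cigar)
    ref_off = path.ref_off
    hap_span = alt_cigar.ref_len  # haplotype bases consumed by the ALT cigar
    if hap_start + hap_span > len(ref_off):
        raise CigarCompositionError(
            f"ALT cigar spans {hap_start}+{hap_span} haplotype bases, "
            f"path has {len(ref_off)}"
        )

    if not path.taken:  # identity composition fast path
        ops = list(alt_cigar.ops)
        lead = 0
        while ops and ops[0][1] == "D":  # unanchored edge deletions
            lead += ops.pop(0)[0]
        while ops and ops[-1][1] == "D":
            ops.pop()
        if not any(op == "M" for _, op in ops):
            raise CigarCompositionError("alignment consumes no reference")
        return int(ref_off[hap_start + lead]), CigarString(ops)

    # events: ("M", read_i, ref_j) | ("I", read_i, -1) | ("D", -1, ref_j) | ("S", n, -1)
    events: list[tuple[str, int, int]] = []
    hap = hap_start
    read_i = 0
    last_ref = -2  # sentinel: no reference base consumed yet

    def cross_to(j: int) -> None:
        nonlocal last_ref
        if last_ref >= 0 and j > last_ref + 1:
            for g in range(last_ref + 1, j):
                events.append(("D", -1, g))
        last_ref = j

    for length, op in alt_cigar.ops:
        if op == "S":
            events.append(("S", length, -1))
            read_i += length
        elif op == "M":
            for _ in range(length):
                j = int(ref_off[hap])
                if j >= 0:
                    cross_to(j)
                    events.append(("M", read_i, j))
                else:
                    events.append(("I", read_i, -1))
                hap += 1
                read_i += 1
        elif op == "I":
            for _ in range(length):
                events.append(("I", read_i, -1))
                read_i += 1
        elif op == "D":
            for _ in range(length):
                j = int(ref_off[hap])
                if j >= 0:
                    cross_to(j)
                    events.append(("D", -1, j))
                # a deleted inserted base restores to nothing
                hap += 1

    runs = _group_runs(events)
    runs = _cancel_adjacent_indels(runs)
    # leading/trailing reference deletions do not anchor an alignment
    while runs and runs[0][0] == "D":
        runs.pop(0)
    while runs and runs[-1][0] == "D":
        runs.pop()
    if not runs:
        raise CigarCompositionError("empty restored alignment")

    ref_pos = -1
    for op, items in runs:
        if op in "MD":
            ref_pos = items[0][2]
            break
    if ref_pos < 0:
        # alignment entirely inside an insertion: anchor after the insertion
        nxt = ref_off[hap_start:]
        real = nxt[nxt >= 0]
        ref_pos = int(real[0]) if len(real) else int(ref_off.max()) + 1

    cigar = CigarString(
        (items[0][1] if op == "S" else len(items), op) for op, items in runs
    )
    return ref_pos, cigar


def _group_runs(events):
    runs: list[tuple[str, list]] = []
    for ev in events:
        if runs and runs[-1][0] == ev[0] and ev[0] != "S":
            runs[-1][1].append(ev)
        else:
            runs.append((ev[0], [ev]))
    return runs


def _cancel_adjacent_indels(runs):
    """Pair adjacent I/D runs base-by-base into M (match-or-mismatch).

    A single left-to-right pass: each adjacent insertion/deletion run pair
    collapses into M for the overlapping length with the leftover kept in
    place; leftovers are not re-paired with later runs.
    """
    out: list[tuple[str, list]] = []
    i = 0
    while i < len(runs):
        op, items = runs[i]
        nxt = runs[i + 1] if i + 1 < len(runs) else None
        if op in "ID" and nxt is not None and nxt[0] in "ID" and nxt[0] != op:
            ins = items if op == "I" else nxt[1]
            dels = items if op == "D" else nxt[1]
            k = min(len(ins), len(dels))
            out.append(("M", [("M", ins[j][1], dels[j][2]) for j in range(k)]))
            if len(ins) > k:
                out.append(("I", list(ins[k:])))
            elif len(dels) > k:
                out.append(("D", list(dels[k:])))
            i += 2
        else:
            out.append((op, list(items)))
            i += 1
    return _merge_same(out)


def _merge_same(runs):
    out: list[tuple[str, list]] = []
    for op, items in runs:
        if out and out[-1][0] == op and op != "S":
            out[-1][1].extend(items)
        else:
            out.append((op, list(items)))
    return out
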