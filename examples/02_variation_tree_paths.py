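"""Build a variation tree over two local windows and enumerate its paths.

Shared prefixes of the window sequences merge into common trie nodes;
attached INDELs become optional edges, and every choice of non-overlapping
INDELs realizes one haplotype path with a unique id.
"""

import io

from varatree import (
    RegionWindow,
    VariantRecord,
    VType,
    build_tree,
    dump_tree,
    enumerate_paths,
    load_reference,
    path_sequence,
)

ref = load_reference(io.StringIO(">a\nACGTAGGA\n>b\nACCTAGGA\n"))
ins = VariantRecord("a", 4, VType.INS, "", "TT", 2, 0)
dele = VariantRecord("a", 5, VType.DEL, "GG", "", 2, 1)

tree = build_tree(
    [
        (RegionWindow("a", 0, 8), ref.codes("a")),
        (RegionWindow("b", 0, 8), ref.codes("b")),
    ],
    variants=[[ins, dele], []],
)
paths = enumerate_paths(tree)

print("tree nodes (id, parent, label, attached variants):")
print(dump_tree(tree))
print()
for p in paths:
    seq, coords = path_sequence(tree, p.id)
    print(f"path {p.id}: variants={p.variant_ids} haplotype={seq}")

# The windows share the node "AC", then branch (children in alphabetical
# order).  Window a carries a 2 bp insertion and a 2 bp deletion, which are
# independent, so it contributes 4 haplotype paths; window b contributes 1.
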