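"""On-disk serialization of the variation-aware index.

An index directory holds a JSON metadata file with a format-version header,
one NPZ with the per-chromosome 4-bit masks and raw sequences, and a
JSON-lines file of INDEL records.  The k-mer seed index is cheap to build
and is reconstructed at map time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import IndexFormatError
from .refvar import AltSeqIndex, VarAwareReference, VariantRecord, VType, _Chrom

FORMAT_VERSION = 1


def save_index(out_dir, ref: VarAwareReference, altseq: AltSeqIndex) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "chromosomes": [{"name": n, "length": l} for n, l in ref.lengths.items()],
        "n_indels": len(altseq),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    arrays = {}
    for n, c in ref.chroms.items():
        arrays[f"masks:{n}"] = c.masks
        arrays[f"seq:{n}"] = np.frombuffer(c.seq.encode(), np.uint8)
    np.savez_compressed(out / "reference.npz", **arrays)
    with open(out / "altseq.jsonl", "w") as fh:
        for r in altseq.records():
            fh.write(
                json.dumps(
                    {
                        "chrom": r.chrom,
                        "pos": r.pos,
                        "vtype": r.vtype.value,
                        "ref": r.ref_allele,
                        "alt": r.alt_allele,
                        "length": r.length,
                        "id": r.id,
                    }
                )
                + "\n"
            )


def load_index(in_dir) -> tuple[VarAwareReference, AltSeqIndex]:
    src = Path(in_dir)
    meta_path = src / "meta.json"
    if not meta_path.exists():
        raise IndexFormatError(f"no index at {src}")
    meta = json.loads(meta_path.read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise IndexFormatError(
            f"format version {meta.get('format_version')} != {FORMAT_VERSION}"
        )
    data = np.load(src / "reference.npz")
    ref = VarAwareReference()
    for entry in meta["chromosomes"]:
        n = entry["name"]
        ref.chroms[n] = _Chrom(data[f"masks:{n}"], data[f"seq:{n}"].tobytes().decode())
    altseq = AltSeqIndex(known_chroms=ref.names)
    with open(src / "altseq.jsonl") as fh:
        for line in fh:
            d = json.loads(line)
            altseq.add(
                VariantRecord(
                    d["chrom"], d["pos"], VType(d["vtype"]), d["ref"], d["alt"],
                    d["length"], d["id"],
                )
            )
    return ref, altseq
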