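"""File formats: FASTA and the aligned-core table.

The aligned-core table is a TSV holding one decomposed sequence per row:
``id, organism, taxonomy, n_ext, core, insertions, c_ext, group, clade``
with taxonomy ranks joined by ';' and insertions encoded ``col:res;col:res``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq_core import CoreAlignedSequence

CORE_TABLE_COLUMNS = (
    "id", "organism", "taxonomy", "n_ext", "core",
    "insertions", "c_ext", "group", "clade",
)


def read_fasta(path) -> dict[str, str]:
    """IDs (verbatim) to sequences."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in items]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def _encode_insertions(ins: dict[int, str]) -> str:
    return ";".join(f"{c}:{r}" for c, r in sorted(ins.items()))


def _decode_insertions(text: str) -> dict[int, str]:
    if not text:
        return {}
    out = {}
    for item in text.split(";"):
        col, res = item.split(":")
        out[int(col)] = res
    return out


def write_core_table(seqs: Sequence[CoreAlignedSequence], path) -> None:
    rows = [
        {
            "id": s.id,
            "organism": s.organism,
            "taxonomy": ";".join(s.taxonomy),
            "n_ext": s.n_ext,
            "core": s.core,
            "insertions": _encode_insertions(s.insertions),
            "c_ext": s.c_ext,
            "group": s.group or "",
            "clade": s.clade or "",
        }
        for s in seqs
    ]
    pd.DataFrame(rows, columns=CORE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_core_table(path) -> list[CoreAlignedSequence]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            CoreAlignedSequence.from_parts(
                id=row["id"],
                core=row["core"],
                insertions=_decode_insertions(row["insertions"]),
                n_ext=row["n_ext"],
                c_ext=row["c_ext"],
                organism=row["organism"],
                taxonomy=tuple(t for t in row["taxonomy"].split(";") if t),
                group=row["group"] or None,
                clade=row["clade"] or None,
            )
        )
    return out
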