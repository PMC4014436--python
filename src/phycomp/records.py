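"""Shared sequence record types and FASTA helpers."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein: identifier, taxon of origin, residues."""

    id: str
    taxon: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqio_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(seqio_records, handle, "fasta")


def read_fasta(path: str | Path, taxon: str) -> list[ProteinRecord]:
    return [ProteinRecord(rec.id, taxon, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]
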