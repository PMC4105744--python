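"""Sequencing-read container and FASTQ/FASTA round-tripping."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .reference_io import normalize_rna


@dataclass(frozen=True)
class Read:
    """One single-end read; qualities are never used downstream."""

    read_id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def read_reads(path: str | Path) -> list[Read]:
    """Load reads from FASTQ or FASTA (decided by file extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [
        Read(rec.id, normalize_rna(str(rec.seq), context=f"read {rec.id!r}"))
        for rec in SeqIO.parse(str(path), fmt)
    ]


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as FASTQ with constant 'I' qualities."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_fasta_reads(reads: Sequence[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.seq}\n")
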