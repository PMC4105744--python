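"""Reference transcript sets and named-region annotations.

The whole pipeline operates on a small set of named RNAs (a pre-rRNA,
snoRNAs, controls) rather than a genome.  Coordinates facing the user are
always 1-based inclusive, the convention used for rRNA features such as
"nucleotides 1051-1070"; 0-based half-open coordinates appear only in
bedGraph output, where the format requires them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

RNA_CLASSES = ("rRNA", "snoRNA", "other")
_VALID = set("ACGU")


class ReferenceError(ValueError):
    """Raised for malformed reference sequences or region annotations."""


def normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, convert T to U and reject anything outside A,C,G,U.

    Ambiguity codes are rejected on purpose: the rDNA/snoRNA targets this
    pipeline handles are unambiguous.
    """
    s = seq.upper().replace("T", "U")
    for pos, ch in enumerate(s, start=1):
        if ch not in _VALID:
            raise ReferenceError(
                f"invalid character {ch!r} at position {pos} in {context}"
            )
    return s


@dataclass(frozen=True)
class Region:
    """A named feature on one RNA, 1-based inclusive (e.g. ES6H3)."""

    rna_id: str
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ReferenceError(
                f"region {self.name!r} on {self.rna_id!r}: "
                f"require 1 <= start <= end, got {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReferenceSet:
    """Named RNA sequences with class labels and named regions."""

    rnas: dict[str, str]
    classes: dict[str, str] = field(default_factory=dict)
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rna_id, seq in self.rnas.items():
            if not rna_id:
                raise ReferenceError("empty rna_id")
            if len(seq) < 1:
                raise ReferenceError(f"empty sequence for {rna_id!r}")
            self.rnas[rna_id] = normalize_rna(seq, context=f"RNA {rna_id!r}")
        for rna_id, cls in self.classes.items():
            if cls not in RNA_CLASSES:
                raise ReferenceError(
                    f"unknown class {cls!r} for {rna_id!r}; "
                    f"expected one of {RNA_CLASSES}"
                )
        for rna_id in self.rnas:
            self.classes.setdefault(rna_id, "other")
        for region in self.regions:
            self._check_region(region)

    def _check_region(self, region: Region) -> None:
        if region.rna_id not in self.rnas:
            raise ReferenceError(
                f"region {region.name!r} references unknown RNA {region.rna_id!r}"
            )
        n = len(self.rnas[region.rna_id])
        if region.end > n:
            raise ReferenceError(
                f"region {region.name!r} ({region.start}..{region.end}) exceeds "
                f"length {n} of RNA {region.rna_id!r}"
            )

    def length(self, rna_id: str) -> int:
        return len(self.rnas[rna_id])

    def ids_of_class(self, cls: str) -> list[str]:
        return [r for r in self.rnas if self.classes.get(r) == cls]

    def regions_on(self, rna_id: str) -> list[Region]:
        return [r for r in self.regions if r.rna_id == rna_id]

    def add_region(self, region: Region) -> None:
        self._check_region(region)
        self.regions.append(region)


def resolve_region(ref: ReferenceSet, rna_id: str, start: int, end: int) -> str:
    """Inclusive subsequence ``start..end`` (1-based) of one RNA, 5'->3'."""
    if rna_id not in ref.rnas:
        raise ReferenceError(f"unknown RNA {rna_id!r}")
    n = len(ref.rnas[rna_id])
    if not (1 <= start <= end <= n):
        raise ReferenceError(
            f"coordinates {start}..{end} out of range for {rna_id!r} (length {n})"
        )
    return ref.rnas[rna_id][start - 1 : end]


def load_reference(fasta_path: str | Path, regions_path: str | Path | None = None) -> ReferenceSet:
    """Load a reference set from FASTA plus an optional regions TSV.

    FASTA descriptions may carry ``class=rRNA|snoRNA|other``; records without
    one default to ``other``.  The regions TSV has a header row with columns
    ``rna_id, name, start, end`` (1-based inclusive).
    """
    rnas: dict[str, str] = {}
    classes: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in rnas:
            raise ReferenceError(f"duplicate rna_id {record.id!r} in {fasta_path}")
        rnas[record.id] = normalize_rna(str(record.seq), context=f"RNA {record.id!r}")
        for token in record.description.split():
            if token.startswith("class="):
                classes[record.id] = token[len("class=") :]
    if not rnas:
        raise ReferenceError(f"no FASTA records in {fasta_path}")

    regions: list[Region] = []
    if regions_path is not None:
        regions = list(_read_regions_tsv(regions_path))
    return ReferenceSet(rnas=rnas, classes=classes, regions=regions)


def _read_regions_tsv(path: str | Path) -> Iterable[Region]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"rna_id", "name", "start", "end"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ReferenceError(
                f"regions file {path} must have header columns {sorted(required)}"
            )
        for row in reader:
            yield Region(
                rna_id=row["rna_id"],
                name=row["name"],
                start=int(row["start"]),
                end=int(row["end"]),
            )


def write_reference(ref: ReferenceSet, fasta_path: str | Path,
                    regions_path: str | Path | None = None,
                    line_width: int = 70) -> None:
    """Write the normalized reference back to FASTA (and regions TSV)."""
    with open(fasta_path, "w") as fh:
        for rna_id, seq in ref.rnas.items():
            fh.write(f">{rna_id} class={ref.classes.get(rna_id, 'other')}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    if regions_path is not None:
        with open(regions_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["rna_id", "name", "start", "end"])
            for r in ref.regions:
                writer.writerow([r.rna_id, r.name, r.start, r.end])


def regions_overlapping(ref: ReferenceSet, rna_id: str, start: int, end: int) -> list[Region]:
    """Named regions on ``rna_id`` overlapping the inclusive interval."""
    return [
        r
        for r in ref.regions_on(rna_id)
        if not (r.end < start or r.start > end)
    ]
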