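"""CLASH chimeric-read detection and hybrid duplex annotation.

A chimeric (hybrid) read arises when two cross-linked RNA fragments are
ligated and sequenced as one molecule: its two arms map to two loci.  Reads
that place full-length on the transcript set are never chimeras; the rest
are searched over every junction that leaves both arms at least
``min_arm_length`` long, each arm placed independently by exhaustive
ungapped scanning.  A detected hybrid can then be annotated with the duplex
minimum free energy between its arms' reference sequences.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .crac_profile import (
    Alignment,
    _RefIndex,
    _placement_to_alignment,
    _scan_read,
    _unique_best,
)
from .duplex_model import EnergyModel, duplex_mfe, default_model
from .reads_io import Read
from .reference_io import ReferenceSet, resolve_region


@dataclass(frozen=True)
class ChimericRead:
    """One read split into two arms aligned to two loci.

    ``junction`` is the 1-based read position where arm_b begins: arm_a
    covers read positions [1, junction-1], arm_b covers [junction, length].
    ``hybrid_mfe`` is the duplex MFE between the arms' reference sequences
    (None until folded, or the no-duplex sentinel stays None).
    """

    read_id: str
    arm_a: Alignment
    arm_b: Alignment
    junction: int
    hybrid_mfe: float | None = None


def _locus_rule_ok(a: Alignment, b: Alignment, min_separation: int) -> bool:
    """Arms must hit different RNAs, or the same RNA > min_separation apart."""
    if a.rna_id != b.rna_id:
        return True
    gap = max(a.start, b.start) - min(a.end, b.end) - 1
    return gap > min_separation


def detect_chimeras(reads: Sequence[Read], ref: ReferenceSet,
                    min_arm_length: int = 17, max_mismatches_per_arm: int = 1,
                    min_same_rna_separation: int = 30,
                    full_length_max_mismatches: int = 2,
                    mismatch_penalty: int = 2,
                    deletion_penalty: int = 2) -> list[ChimericRead]:
    """Detect two-arm chimeric reads on the transcript set.

    For each read failing full-length placement, every junction j with both
    arms >= min_arm_length is tried; a chimera is emitted iff some j gives
    unique best ungapped placements for both arms satisfying the
    different-locus rule.  Among valid junctions the one maximizing total
    matched bases wins, ties broken toward the smallest junction.  Output
    order follows input order; the detected set is per-read independent and
    hence invariant under input reordering.
    """
    from .duplex_model import encode

    idx = _RefIndex(ref)
    out: list[ChimericRead] = []
    for read in reads:
        L = len(read)
        if L < 2 * min_arm_length:
            continue
        readc = encode(read.seq)
        full = _scan_read(idx, readc, full_length_max_mismatches, with_deletion=True)
        if full:
            continue  # reads that map full-length are never chimeras
        best_choice: tuple[int, int, Alignment, Alignment] | None = None
        for j in range(min_arm_length, L - min_arm_length + 1):
            arm_a_c, arm_b_c = readc[:j], readc[j:]
            pa = _unique_best(
                _scan_read(idx, arm_a_c, max_mismatches_per_arm, with_deletion=False),
                j, mismatch_penalty, deletion_penalty)
            if pa is None:
                continue
            pb = _unique_best(
                _scan_read(idx, arm_b_c, max_mismatches_per_arm, with_deletion=False),
                L - j, mismatch_penalty, deletion_penalty)
            if pb is None:
                continue
            a = _placement_to_alignment(Read(read.read_id, read.seq[:j]), arm_a_c,
                                        idx, pa, mismatch_penalty, deletion_penalty)
            b = _placement_to_alignment(Read(read.read_id, read.seq[j:]), arm_b_c,
                                        idx, pb, mismatch_penalty, deletion_penalty)
            if not _locus_rule_ok(a, b, min_same_rna_separation):
                continue
            matched = L - pa.n_mismatches - pb.n_mismatches
            cand = (-matched, j, a, b)
            if best_choice is None or cand[:2] < best_choice[:2]:
                best_choice = cand
        if best_choice is not None:
            _, j, a, b = best_choice
            out.append(ChimericRead(read_id=read.read_id, arm_a=a, arm_b=b,
                                    junction=j + 1))
    return out


def fold_hybrid(c: ChimericRead, ref: ReferenceSet,
                m: EnergyModel | None = None, flank: int = 0) -> ChimericRead:
    """Annotate a chimera with the duplex MFE of its arms' reference
    sequences, each extended by ``flank`` nucleotides (truncated at the
    RNA bounds).  A no-duplex result leaves hybrid_mfe as None."""
    m = m or default_model()

    def arm_seq(a: Alignment) -> str:
        lo = max(1, a.start - flank)
        hi = min(ref.length(a.rna_id), a.end + flank)
        return resolve_region(ref, a.rna_id, lo, hi)

    result = duplex_mfe(arm_seq(c.arm_a), arm_seq(c.arm_b), m)
    return replace(c, hybrid_mfe=result.energy)


def write_hybrids_tsv(chimeras: Sequence[ChimericRead], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "rna_a", "a_start", "a_end", "rna_b", "b_start",
                    "b_end", "junction", "mfe_kcal_mol"])
        for c in chimeras:
            w.writerow([c.read_id, c.arm_a.rna_id, c.arm_a.start, c.arm_a.end,
                        c.arm_b.rna_id, c.arm_b.start, c.arm_b.end, c.junction,
                        "NA" if c.hybrid_mfe is None else f"{c.hybrid_mfe:.2f}"])


def read_hybrids_tsv(path: str | Path) -> list[ChimericRead]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            arm_a = Alignment(row["read_id"], row["rna_a"], int(row["a_start"]),
                              int(row["a_end"]))
            arm_b = Alignment(row["read_id"], row["rna_b"], int(row["b_start"]),
                              int(row["b_end"]))
            mfe = None if row["mfe_kcal_mol"] == "NA" else float(row["mfe_kcal_mol"])
            out.append(ChimericRead(row["read_id"], arm_a, arm_b,
                                    int(row["junction"]), mfe))
    return out
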