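"""Per-nucleotide cross-linking profiles from sequencing reads.

Reads are placed on the transcript set by exhaustive ungapped scanning
(optionally with one single-nucleotide reference deletion, the signature
left by reverse transcription at a cross-linked base).  Placements are
scored, the unique best is kept, and multi-mapping reads are discarded.
Alignments become hits-per-million coverage tracks and mutation tracks;
peaks are maximal runs above a fraction of the highest per-nucleotide
value (5% by default), optionally flagged when shared with an untagged
control; per-snoRNA enrichment summarizes relative cross-linking.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .reads_io import Read
from .reference_io import ReferenceSet, regions_overlapping
from .duplex_model import encode


@dataclass(frozen=True)
class Alignment:
    """An ungapped read placement, possibly with one reference deletion.

    Coordinates are 1-based inclusive on the reference; ``mismatches`` and
    ``deletions`` hold reference positions.  ``score = matches
    - mismatch_penalty * n_mismatches - deletion_penalty * n_deletions``.
    """

    read_id: str
    rna_id: str
    start: int
    end: int
    mismatches: tuple[int, ...] = ()
    deletions: tuple[int, ...] = ()
    score: int = 0

    @property
    def aligned_length(self) -> int:
        return self.end - self.start + 1


@dataclass
class NucleotideTrack:
    """One number per nucleotide of one RNA."""

    rna_id: str
    values: np.ndarray
    kind: str  # coverage_hpm | mutation_count | mutation_rate


@dataclass
class Peak:
    """A maximal run of nucleotides at or above the calling threshold."""

    rna_id: str
    start: int
    end: int
    max_height_hpm: float
    relative_height: float
    control_flag: bool = False


def filter_reads(reads: Sequence[Read], min_length: int = 17) -> list[Read]:
    """Length filter standing in for adapter/quality pre-processing."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    return [r for r in reads if len(r) >= min_length]


class _RefIndex:
    """Encoded reference sequences shared by the mapping scans."""

    def __init__(self, ref: ReferenceSet):
        self.ref = ref
        self.codes = {rna_id: encode(seq) for rna_id, seq in ref.rnas.items()}


def _ungapped_mismatches(refc: np.ndarray, readc: np.ndarray) -> np.ndarray:
    """Mismatch count of the read at every start (0-based) of one RNA."""
    L = readc.shape[0]
    if refc.shape[0] < L:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(refc, L)
    return (windows != readc).sum(axis=1)


def _deletion_mismatches(refc: np.ndarray, readc: np.ndarray) -> np.ndarray:
    """Mismatches for placements spanning L+1 reference nts with one
    internal reference position skipped.

    Returns an (n_starts, L-1) matrix: entry (s, d-1) is the mismatch count
    when reference position s+d (0-based) is deleted, d in 1..L-1.
    """
    L = readc.shape[0]
    if L < 2 or refc.shape[0] < L + 1:
        return np.empty((0, 0), dtype=np.int64)
    W = sliding_window_view(refc, L + 1)
    neq_pre = (W[:, :L] != readc).astype(np.int64)
    neq_suf = (W[:, 1:] != readc).astype(np.int64)
    P = np.cumsum(neq_pre, axis=1)          # P[:, d-1] = mm of read[0:d]
    S = np.cumsum(neq_suf[:, ::-1], axis=1)[:, ::-1]  # S[:, d] = mm of read[d:]
    return P[:, : L - 1] + S[:, 1:]


@dataclass(frozen=True)
class _Placement:
    rna_id: str
    start: int          # 1-based
    del_offset: int     # 0 = ungapped, else deleted ref offset 1..L-1
    n_mismatches: int


def _scan_read(idx: _RefIndex, readc: np.ndarray, max_mismatches: int,
               with_deletion: bool) -> list[_Placement]:
    """All placements of one read with <= max_mismatches."""
    out: list[_Placement] = []
    for rna_id, refc in idx.codes.items():
        mm = _ungapped_mismatches(refc, readc)
        for s in np.nonzero(mm <= max_mismatches)[0]:
            out.append(_Placement(rna_id, int(s) + 1, 0, int(mm[s])))
    if with_deletion and not any(p.n_mismatches == 0 and p.del_offset == 0
                                 for p in out):
        for rna_id, refc in idx.codes.items():
            dm = _deletion_mismatches(refc, readc)
            if dm.size == 0:
                continue
            ss, dd = np.nonzero(dm <= max_mismatches)
            for s, d in zip(ss, dd):
                out.append(_Placement(rna_id, int(s) + 1, int(d) + 1, int(dm[s, d])))
    return out


def _placement_score(p: _Placement, read_len: int, mismatch_penalty: int,
                     deletion_penalty: int) -> int:
    n_del = 1 if p.del_offset else 0
    matches = read_len - p.n_mismatches
    return matches - mismatch_penalty * p.n_mismatches - deletion_penalty * n_del


def _unique_best(placements: list[_Placement], read_len: int,
                 mismatch_penalty: int, deletion_penalty: int) -> _Placement | None:
    """Best-scoring placement, or None when tied across distinct loci.

    Ties at the same (rna_id, start) prefer the ungapped placement, then the
    smallest deletion offset; ties across distinct loci mean multi-mapping.
    """
    if not placements:
        return None
    best = max(_placement_score(p, read_len, mismatch_penalty, deletion_penalty)
               for p in placements)
    top = [p for p in placements
           if _placement_score(p, read_len, mismatch_penalty, deletion_penalty) == best]
    loci = {(p.rna_id, p.start) for p in top}
    if len(loci) > 1:
        return None
    return min(top, key=lambda p: p.del_offset)


def _placement_to_alignment(read: Read, readc: np.ndarray, idx: _RefIndex,
                            p: _Placement, mismatch_penalty: int,
                            deletion_penalty: int) -> Alignment:
    L = readc.shape[0]
    refc = idx.codes[p.rna_id]
    if p.del_offset == 0:
        span = refc[p.start - 1 : p.start - 1 + L]
        mism = tuple(p.start + int(k) for k in np.nonzero(span != readc)[0])
        dels: tuple[int, ...] = ()
        end = p.start + L - 1
    else:
        d = p.del_offset
        span = refc[p.start - 1 : p.start + L]
        keep = np.concatenate([span[:d], span[d + 1 :]])
        ref_pos = np.concatenate([np.arange(0, d), np.arange(d + 1, L + 1)])
        mism = tuple(p.start + int(ref_pos[k])
                     for k in np.nonzero(keep != readc)[0])
        dels = (p.start + d,)
        end = p.start + L
    score = _placement_score(p, L, mismatch_penalty, deletion_penalty)
    return Alignment(read_id=read.read_id, rna_id=p.rna_id, start=p.start,
                     end=end, mismatches=mism, deletions=dels, score=score)


def map_reads(reads: Sequence[Read], ref: ReferenceSet, max_mismatches: int = 2,
              min_aligned_length: int = 17, mismatch_penalty: int = 2,
              deletion_penalty: int = 2,
              allow_deletion: bool = True) -> list[Alignment]:
    """Place each read at its unique best-scoring locus on the transcript set.

    Exhaustive ungapped end-to-end placement over every RNA, plus placements
    with one single-nucleotide reference deletion; reads whose best score is
    achieved at more than one locus are discarded as multi-mapped, and
    unplaceable or too-short reads are dropped silently.
    """
    idx = _RefIndex(ref)
    out: list[Alignment] = []
    for read in reads:
        if len(read) < min_aligned_length:
            continue
        readc = encode(read.seq)
        placements = _scan_read(idx, readc, max_mismatches, allow_deletion)
        best = _unique_best(placements, len(read), mismatch_penalty, deletion_penalty)
        if best is None:
            continue
        out.append(_placement_to_alignment(read, readc, idx, best,
                                           mismatch_penalty, deletion_penalty))
    return out


def _coverage_counts(alignments: Iterable[Alignment], ref: ReferenceSet) -> dict[str, np.ndarray]:
    counts = {rna_id: np.zeros(ref.length(rna_id) + 1) for rna_id in ref.rnas}
    for a in alignments:
        delta = counts[a.rna_id]
        delta[a.start - 1] += 1
        delta[a.end] -= 1
    return {rna_id: np.cumsum(d)[:-1] for rna_id, d in counts.items()}


def build_coverage(alignments: Sequence[Alignment], ref: ReferenceSet,
                   total_reads: int | None = None) -> dict[str, NucleotideTrack]:
    """Hits-per-million coverage: every covered nucleotide of every
    alignment counts one hit, scaled by 1e6 / total.

    ``total_reads`` defaults to the number of mapped reads (hits per million
    mapped reads); pass the library size to normalize per million raw reads
    instead.
    """
    if not alignments:
        raise ValueError("no alignments: hits-per-million is undefined")
    total = total_reads if total_reads is not None else len(alignments)
    scale = 1e6 / total
    counts = _coverage_counts(alignments, ref)
    return {
        rna_id: NucleotideTrack(rna_id, c * scale, "coverage_hpm")
        for rna_id, c in counts.items()
    }


def build_mutation_profile(alignments: Sequence[Alignment], ref: ReferenceSet,
                           ) -> tuple[dict[str, NucleotideTrack], dict[str, NucleotideTrack]]:
    """Per-nucleotide mutation counts and rates.

    A substitution or a deletion recorded at a reference position counts one
    mutation there; the rate divides by the number of alignments covering
    the position (0 where nothing aligns).
    """
    counts = {rna_id: np.zeros(ref.length(rna_id)) for rna_id in ref.rnas}
    for a in alignments:
        for pos in a.mismatches + a.deletions:
            counts[a.rna_id][pos - 1] += 1
    cov = _coverage_counts(alignments, ref) if alignments else {
        rna_id: np.zeros(ref.length(rna_id)) for rna_id in ref.rnas
    }
    count_tracks, rate_tracks = {}, {}
    for rna_id, c in counts.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(cov[rna_id] > 0, c / np.maximum(cov[rna_id], 1), 0.0)
        count_tracks[rna_id] = NucleotideTrack(rna_id, c, "mutation_count")
        rate_tracks[rna_id] = NucleotideTrack(rna_id, rate, "mutation_rate")
    return count_tracks, rate_tracks


def call_peaks(tracks: dict[str, NucleotideTrack], threshold_fraction: float = 0.05,
               scope_rna_ids: Sequence[str] | None = None) -> list[Peak]:
    """Maximal runs of nucleotides at or above a fraction of the maximum.

    The threshold is ``threshold_fraction`` times the highest per-nucleotide
    value across ``scope_rna_ids`` (all tracks by default); peaks are called
    within the scope and report their height relative to that maximum.
    All-zero tracks yield an empty peak list.
    """
    if not tracks:
        raise ValueError("no tracks")
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    scope = list(scope_rna_ids) if scope_rna_ids is not None else list(tracks)
    missing = [r for r in scope if r not in tracks]
    if missing:
        raise ValueError(f"scope RNAs without tracks: {missing}")
    global_max = max(float(tracks[r].values.max()) for r in scope)
    if global_max <= 0:
        return []
    threshold = threshold_fraction * global_max
    peaks: list[Peak] = []
    for rna_id in scope:
        v = tracks[rna_id].values
        above = v >= threshold
        edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        for s, e in zip(starts, ends):
            height = float(v[s:e].max())
            peaks.append(Peak(rna_id=rna_id, start=int(s) + 1, end=int(e),
                              max_height_hpm=height,
                              relative_height=height / global_max))
    return peaks


def flag_control_peaks(peaks: Sequence[Peak], control_peaks: Sequence[Peak],
                       min_overlap_fraction: float = 0.5) -> list[Peak]:
    """Flag peaks whose nucleotides lie mostly inside untagged-control peaks.

    A peak is flagged iff at least ``min_overlap_fraction`` of its
    nucleotides fall inside the union of control peaks on the same RNA
    (boundary inclusive).
    """
    flagged = []
    for p in peaks:
        n = p.end - p.start + 1
        inside = np.zeros(n, dtype=bool)
        for c in control_peaks:
            if c.rna_id != p.rna_id or c.end < p.start or c.start > p.end:
                continue
            lo = max(p.start, c.start) - p.start
            hi = min(p.end, c.end) - p.start
            inside[lo : hi + 1] = True
        flagged.append(replace(p, control_flag=inside.sum() / n >= min_overlap_fraction))
    return flagged


def snorna_enrichment(alignments: Sequence[Alignment], ref: ReferenceSet):
    """Relative cross-linking per snoRNA: reads per million mapped,
    divided by the maximum across snoRNA-class RNAs (values in [0, 1])."""
    import pandas as pd

    sno = ref.ids_of_class("snoRNA")
    if not sno:
        raise ValueError("reference contains no snoRNA-class RNA")
    total = len(alignments)
    counts = {rna_id: 0 for rna_id in sno}
    for a in alignments:
        if a.rna_id in counts:
            counts[a.rna_id] += 1
    rpm = {r: (1e6 * c / total if total else 0.0) for r, c in counts.items()}
    top = max(rpm.values())
    rel = {r: (v / top if top > 0 else 0.0) for r, v in rpm.items()}
    return pd.DataFrame({
        "rna_id": sno,
        "reads": [counts[r] for r in sno],
        "rpm": [rpm[r] for r in sno],
        "relative": [rel[r] for r in sno],
    })


def write_bedgraph(track: NucleotideTrack, path: str | Path) -> None:
    """bedGraph export (0-based half-open, as the format requires)."""
    v = track.values
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.rna_id}:{track.kind}"\n')
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[j + 1] == v[i]:
                j += 1
            if v[i] != 0:
                fh.write(f"{track.rna_id}\t{i}\t{j + 1}\t{v[i]:g}\n")
            i = j + 1


def write_peaks_tsv(peaks: Sequence[Peak], ref: ReferenceSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["rna_id", "start", "end", "height_hpm", "relative_height",
                    "control_flag", "regions"])
        for p in peaks:
            names = ",".join(r.name for r in
                             regions_overlapping(ref, p.rna_id, p.start, p.end))
            w.writerow([p.rna_id, p.start, p.end, f"{p.max_height_hpm:.3f}",
                        f"{p.relative_height:.4f}", int(p.control_flag), names])


def read_peaks_tsv(path: str | Path) -> list[Peak]:
    peaks = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            peaks.append(Peak(rna_id=row["rna_id"], start=int(row["start"]),
                              end=int(row["end"]),
                              max_height_hpm=float(row["height_hpm"]),
                              relative_height=float(row["relative_height"]),
                              control_flag=bool(int(row["control_flag"]))))
    return peaks
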