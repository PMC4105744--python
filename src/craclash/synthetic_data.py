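"""Synthetic references, planted interactions and simulated CRAC/CLASH reads.

Every downstream stage of the pipeline is exercised against data generated
here, with a full ground-truth record: planted protein-binding sites with a
designated cross-link position (where reverse transcription introduces
substitutions or single-nucleotide deletions), and planted intermolecular
duplexes expressed both as sequence complementarity and as chimeric reads
ligated from two RNA fragments.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; a fixed seed reproduces byte-identical FASTQ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .reads_io import Read
from .reference_io import ReferenceSet, Region

_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA sequence (A<->U, G<->C)."""
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass
class SimulationConfig:
    """Knobs of the read simulator.

    crosslink_rate is the probability that a read covering a planted
    cross-link position carries a reverse-transcription mutation there;
    deletion_fraction is the fraction of those mutations that are
    single-nucleotide deletions (the rest are substitutions).
    """

    seed: int = 0
    gc_content: float = 0.5
    read_length_range: tuple[int, int] = (20, 30)
    n_reads: int = 10_000
    crosslink_rate: float = 0.3
    deletion_fraction: float = 0.2
    background_error_rate: float = 0.001
    chimera_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("gc_content", "crosslink_rate", "deletion_fraction",
                     "background_error_rate", "chimera_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.read_length_range
        if not (1 <= lo <= hi):
            raise ValueError("read_length_range must satisfy 1 <= min <= max")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass(frozen=True)
class BindingSite:
    """A planted protein-binding interval with one cross-link position."""

    rna_id: str
    start: int
    end: int
    weight: float
    crosslink_pos: int

    def __post_init__(self) -> None:
        if not (self.start <= self.crosslink_pos <= self.end):
            raise ValueError("crosslink_pos must lie inside the binding interval")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass(frozen=True)
class PlantedDuplex:
    """Ground truth for one planted intermolecular duplex."""

    query_rna: str
    q_start: int
    q_end: int
    target_rna: str
    t_start: int
    t_end: int
    length: int
    wobble_positions: tuple[int, ...] = ()  # offsets 0..length-1, target axis


@dataclass
class ReadTruth:
    """Per-read provenance: origin locus/loci and applied mutations."""

    read_id: str
    kind: str  # "site" | "background" | "chimera"
    rna_id: str | None = None
    start: int | None = None
    end: int | None = None
    site_index: int | None = None
    truncated: bool = False
    crosslink_mutated: bool = False
    mutations: list[tuple[int, str]] = field(default_factory=list)  # (ref pos, kind)
    # chimera-only fields
    arm_a: tuple[str, int, int] | None = None
    arm_b: tuple[str, int, int] | None = None
    junction: int | None = None  # 1-based read position where arm_b begins
    duplex_index: int | None = None


@dataclass
class TruthRecord:
    """Everything planted: sites, duplexes and per-read provenance."""

    binding_sites: list[BindingSite] = field(default_factory=list)
    duplexes: list[PlantedDuplex] = field(default_factory=list)
    reads: list[ReadTruth] = field(default_factory=list)

    def merged_with(self, other: "TruthRecord") -> "TruthRecord":
        return TruthRecord(
            binding_sites=self.binding_sites + other.binding_sites,
            duplexes=self.duplexes + other.duplexes,
            reads=self.reads + other.reads,
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def generate_reference(seed: int, spec: list[tuple[str, int, str]],
                       gc_content: float = 0.5) -> ReferenceSet:
    """Random i.i.d. reference RNAs at a given GC content.

    ``spec`` lists (rna_id, length, class) with class one of
    rRNA/snoRNA/other.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    if len({s[0] for s in spec}) != len(spec):
        raise ValueError("duplicate rna_id in reference spec")
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])
    rnas: dict[str, str] = {}
    classes: dict[str, str] = {}
    for rna_id, length, cls in spec:
        if length < 1:
            raise ValueError(f"length must be >= 1 for {rna_id!r}")
        rnas[rna_id] = "".join(rng.choice(_BASES, size=length, p=p))
        classes[rna_id] = cls
    return ReferenceSet(rnas=rnas, classes=classes)


def plant_interaction(ref: ReferenceSet, target: tuple[str, int],
                      query: tuple[str, int], length: int,
                      gu_fraction: float = 0.0, seed: int = 0,
                      guard_flanks: int = 2) -> tuple[ReferenceSet, TruthRecord]:
    """Write a complementary duplex into the reference and record the truth.

    The query interval receives the reverse complement of the target
    interval (antiparallel pairing); ``round(gu_fraction * length)``
    positions are then converted to G:U wobbles by a seeded draw (possible
    only where the target base is G or U).  ``guard_flanks`` nucleotides on
    each side of both intervals are set to A so the planted helix cannot be
    extended by chance complementarity of the flanks: the recorded duplex
    length is exact by construction.
    """
    rng = np.random.default_rng(seed)
    t_rna, t_start = target
    q_rna, q_start = query
    t_end, q_end = t_start + length - 1, q_start + length - 1
    for rna_id, s, e in ((t_rna, t_start, t_end), (q_rna, q_start, q_end)):
        if rna_id not in ref.rnas:
            raise ValueError(f"unknown RNA {rna_id!r}")
        if not (1 <= s <= e <= ref.length(rna_id)):
            raise ValueError(f"interval {s}..{e} out of bounds on {rna_id!r}")
    if t_rna == q_rna and not (t_end < q_start or q_end < t_start):
        raise ValueError("target and query intervals overlap on the same RNA")

    rnas = dict(ref.rnas)
    target_seq = rnas[t_rna][t_start - 1 : t_end]
    planted = list(revcomp(target_seq))  # planted[k] pairs target_seq[length-1-k]

    n_wobble = round(gu_fraction * length)
    eligible = [k for k, base in enumerate(target_seq) if base in "GU"]
    if n_wobble > len(eligible):
        raise ValueError(
            f"gu_fraction {gu_fraction} asks for {n_wobble} wobbles but only "
            f"{len(eligible)} target positions are G or U"
        )
    wobble = tuple(sorted(rng.choice(eligible, size=n_wobble, replace=False).tolist()))
    for k in wobble:
        # target G : query C->U, target U : query A->G (still a legal pair)
        q_off = length - 1 - k
        planted[q_off] = "U" if target_seq[k] == "G" else "G"

    def splice(seq: str, start: int, end: int, repl: str) -> str:
        return seq[: start - 1] + repl + seq[end:]

    def guard(seq: str, start: int, end: int) -> str:
        lo, hi = max(1, start - guard_flanks), min(len(seq), end + guard_flanks)
        left = "A" * (start - lo)
        right = "A" * (hi - end)
        return seq[: lo - 1] + left + seq[start - 1 : end] + right + seq[hi:]

    rnas[q_rna] = splice(rnas[q_rna], q_start, q_end, "".join(planted))
    rnas[q_rna] = guard(rnas[q_rna], q_start, q_end)
    rnas[t_rna] = guard(rnas[t_rna], t_start, t_end)

    new_ref = ReferenceSet(rnas=rnas, classes=dict(ref.classes),
                           regions=list(ref.regions))
    truth = TruthRecord(duplexes=[PlantedDuplex(
        query_rna=q_rna, q_start=q_start, q_end=q_end,
        target_rna=t_rna, t_start=t_start, t_end=t_end,
        length=length, wobble_positions=wobble,
    )])
    return new_ref, truth


def _apply_mutations(seq: str, start: int, rna_seq: str, rng: np.random.Generator,
                     cfg: SimulationConfig,
                     crosslink_positions: list[int]) -> tuple[str, list[tuple[int, str]], bool]:
    """Apply cross-link and background mutations; positions are reference coords."""
    muts: list[tuple[int, str]] = []
    chars = list(seq)
    offsets: dict[int, int] = {}  # ref pos -> index in chars
    for k in range(len(seq)):
        offsets[start + k] = k
    crosslinked = False
    deleted: set[int] = set()
    for pos in crosslink_positions:
        if pos in offsets and rng.random() < cfg.crosslink_rate:
            crosslinked = True
            if rng.random() < cfg.deletion_fraction:
                deleted.add(offsets[pos])
                muts.append((pos, "deletion"))
            else:
                old = chars[offsets[pos]]
                chars[offsets[pos]] = rng.choice([b for b in "ACGU" if b != old])
                muts.append((pos, "substitution"))
    if cfg.background_error_rate > 0:
        mutated = {offsets[p] for p, _ in muts}
        hits = np.nonzero(rng.random(len(chars)) < cfg.background_error_rate)[0]
        for k in hits:
            if k in mutated or k in deleted:
                continue
            old = chars[k]
            chars[k] = rng.choice([b for b in "ACGU" if b != old])
            muts.append((start + int(k), "substitution"))
    out = "".join(c for k, c in enumerate(chars) if k not in deleted)
    return out, sorted(muts), crosslinked


def simulate_crac_reads(ref: ReferenceSet, binding_profile: list[BindingSite],
                        cfg: SimulationConfig, background_weight: float = 0.0,
                        ) -> tuple[list[Read], TruthRecord]:
    """Simulate single-end CRAC reads from a weighted mixture of sites.

    Read starts are uniform within each site interval (or uniform over the
    whole reference for the background component); lengths are uniform in
    ``cfg.read_length_range`` and truncated (and flagged) at the RNA 3' end.
    Reads covering a planted cross-link position carry a mutation there with
    probability ``cfg.crosslink_rate``; independent per-base background
    substitutions are added at ``cfg.background_error_rate``.
    """
    for site in binding_profile:
        if site.rna_id not in ref.rnas:
            raise ValueError(f"unknown RNA {site.rna_id!r} in binding profile")
        if not (1 <= site.start <= site.end <= ref.length(site.rna_id)):
            raise ValueError(f"site {site.rna_id}:{site.start}-{site.end} out of bounds")
    weights = np.array([s.weight for s in binding_profile] + [background_weight],
                       dtype=float)
    if weights.sum() <= 0:
        raise ValueError("at least one positive weight required")
    weights = weights / weights.sum()

    crosslinks: dict[str, list[int]] = {}
    for s in binding_profile:
        crosslinks.setdefault(s.rna_id, []).append(s.crosslink_pos)

    rng = np.random.default_rng(cfg.seed)
    rna_ids = list(ref.rnas)
    rna_lengths = np.array([ref.length(r) for r in rna_ids], dtype=float)
    lo, hi = cfg.read_length_range

    reads: list[Read] = []
    truth = TruthRecord(binding_sites=list(binding_profile))
    for i in range(cfg.n_reads):
        comp = int(rng.choice(len(weights), p=weights))
        if comp < len(binding_profile):
            site = binding_profile[comp]
            rna_id = site.rna_id
            start = int(rng.integers(site.start, site.end + 1))
            site_index = comp
        else:
            rna_id = rna_ids[int(rng.choice(len(rna_ids),
                                            p=rna_lengths / rna_lengths.sum()))]
            start = int(rng.integers(1, ref.length(rna_id) + 1))
            site_index = None
        length = int(rng.integers(lo, hi + 1))
        rna_seq = ref.rnas[rna_id]
        end = min(start + length - 1, len(rna_seq))
        truncated = end < start + length - 1
        raw = rna_seq[start - 1 : end]
        seq, muts, crosslinked = _apply_mutations(
            raw, start, rna_seq, rng, cfg, crosslinks.get(rna_id, [])
        )
        read_id = f"crac_{i:06d}"
        reads.append(Read(read_id, seq))
        truth.reads.append(ReadTruth(
            read_id=read_id, kind="site" if site_index is not None else "background",
            rna_id=rna_id, start=start, end=end, site_index=site_index,
            truncated=truncated, crosslink_mutated=crosslinked, mutations=muts,
        ))
    return reads, truth


def simulate_chimeric_reads(ref: ReferenceSet, duplex_truth: TruthRecord,
                            cfg: SimulationConfig, n_chimeras: int | None = None,
                            canonical_min_arm: int = 17,
                            ) -> tuple[list[Read], TruthRecord]:
    """Simulate chimeric CLASH reads over the planted duplexes.

    Each chimera concatenates (5'->3') one fragment overlapping the query
    arm of a planted duplex and one overlapping its target arm, in random
    order; fragment lengths are drawn from ``cfg.read_length_range`` and the
    fragment fully contains the arm whenever it is long enough (otherwise it
    lies inside the arm).  The truth stores both arm loci and the junction
    (1-based read position where the second arm begins).

    The junction of a chimera is only identifiable up to boundary-base
    ambiguity: when the last base of the first fragment equals the
    reference base immediately preceding the second fragment, the same read
    is equally explained by a junction one position to the left.  Truth
    records therefore store the leftmost equivalent junction (never
    shrinking the first arm below ``canonical_min_arm``), the same
    canonical form a split-read search reports.
    """
    if not duplex_truth.duplexes:
        raise ValueError("no planted duplexes to simulate chimeras from")
    if n_chimeras is None:
        n_chimeras = round(cfg.n_reads * cfg.chimera_fraction)
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.read_length_range

    def fragment(rna_id: str, a_start: int, a_end: int) -> tuple[int, int]:
        L = ref.length(rna_id)
        f = int(rng.integers(lo, hi + 1))
        arm_len = a_end - a_start + 1
        if f >= arm_len:
            lo_s = max(1, a_end - f + 1)
            hi_s = min(a_start, L - f + 1)
            if hi_s < lo_s:
                start = max(1, min(lo_s, L - f + 1))
            else:
                start = int(rng.integers(lo_s, hi_s + 1))
        else:
            start = int(rng.integers(a_start, a_end - f + 2))
        return start, min(start + f - 1, L)

    reads: list[Read] = []
    truth = TruthRecord()
    for i in range(n_chimeras):
        d_idx = int(rng.integers(len(duplex_truth.duplexes)))
        d = duplex_truth.duplexes[d_idx]
        q_loc = (d.query_rna,) + fragment(d.query_rna, d.q_start, d.q_end)
        t_loc = (d.target_rna,) + fragment(d.target_rna, d.t_start, d.t_end)
        first, second = (q_loc, t_loc) if rng.random() < 0.5 else (t_loc, q_loc)
        seq_a = ref.rnas[first[0]][first[1] - 1 : first[2]]
        seq_b = ref.rnas[second[0]][second[1] - 1 : second[2]]
        raw = seq_a + seq_b
        # canonicalize: shift the junction left while the boundary base is
        # ambiguous between the two arms
        f_rna, f_start, f_end = first
        s_rna, s_start, s_end = second
        while (f_end - f_start + 1 > canonical_min_arm and s_start > 1
               and ref.rnas[f_rna][f_end - 1] == ref.rnas[s_rna][s_start - 2]):
            f_end -= 1
            s_start -= 1
        first = (f_rna, f_start, f_end)
        second = (s_rna, s_start, s_end)
        muts: list[tuple[int, str]] = []
        chars = list(raw)
        if cfg.background_error_rate > 0:
            hits = np.nonzero(rng.random(len(chars)) < cfg.background_error_rate)[0]
            for k in hits:
                old = chars[k]
                chars[k] = rng.choice([b for b in "ACGU" if b != old])
                muts.append((int(k) + 1, "substitution"))  # read coordinate
        read_id = f"chimera_{i:06d}"
        reads.append(Read(read_id, "".join(chars)))
        truth.reads.append(ReadTruth(
            read_id=read_id, kind="chimera",
            arm_a=first, arm_b=second, junction=f_end - f_start + 2,
            duplex_index=d_idx, mutations=muts,
        ))
    return reads, truth


def standard_scenario(seed: int, *, rrna_len: int = 1800, snor_len: int = 300,
                      site_weight: float = 20.0, background_weight: float = 1.0,
                      duplex_len: int = 19, gu_fraction: float = 0.0,
                      cfg: SimulationConfig | None = None,
                      ) -> tuple[ReferenceSet, list[BindingSite], TruthRecord, SimulationConfig, float]:
    """A ready-made study-like reference: one pre-rRNA-like RNA with a
    planted protein-binding site, three snoRNA-class RNAs, and one planted
    snoRNA/rRNA duplex with named regions on both RNAs.

    Returns (reference, binding profile, duplex truth, config,
    background_weight).  Used by the CLI ``simulate`` subcommand, the
    examples and the acceptance script.
    """
    rng = np.random.default_rng(seed)
    cfg = cfg or SimulationConfig(seed=seed)
    ref = generate_reference(seed, [
        ("rRNA_18S", rrna_len, "rRNA"),
        ("snoRNA_A", snor_len, "snoRNA"),
        ("snoRNA_B", snor_len, "snoRNA"),
        ("snoRNA_C", snor_len, "snoRNA"),
    ], gc_content=cfg.gc_content)

    # GC-rich target interval so the planted duplex clears the scan cutoff
    t_start = int(rng.integers(200, rrna_len - 400))
    q_start = int(rng.integers(50, snor_len - duplex_len - 50))
    gc_rich = "".join(rng.choice(_BASES, size=duplex_len,
                                 p=np.array([0.1, 0.4, 0.4, 0.1])))
    rnas = dict(ref.rnas)
    rnas["rRNA_18S"] = (rnas["rRNA_18S"][: t_start - 1] + gc_rich
                        + rnas["rRNA_18S"][t_start - 1 + duplex_len :])
    ref = ReferenceSet(rnas=rnas, classes=dict(ref.classes))
    ref, duplex_truth = plant_interaction(
        ref, target=("rRNA_18S", t_start), query=("snoRNA_A", q_start),
        length=duplex_len, gu_fraction=gu_fraction, seed=seed,
    )
    d = duplex_truth.duplexes[0]
    ref.add_region(Region("rRNA_18S", "ES6H3", d.t_start, d.t_end))
    ref.add_region(Region("snoRNA_A", "m1", d.q_start, d.q_end))

    # binding site over the duplex target; the cross-link goes to the
    # position nearest the center whose base differs from both neighbors,
    # so that a reverse-transcription deletion there is unambiguous
    # (a deletion inside a homopolymer run is not attributable to one
    # position and left-aligns away from the cross-link)
    seq = ref.rnas["rRNA_18S"]
    center = (d.t_start + d.t_end) // 2
    crosslink = center
    for delta in range(0, duplex_len):
        for p in (center + delta, center - delta):
            if d.t_start <= p <= d.t_end and seq[p - 2] != seq[p - 1] != seq[p]:
                crosslink = p
                break
        else:
            continue
        break
    site = BindingSite("rRNA_18S", d.t_start - 5, d.t_end + 5,
                       weight=site_weight, crosslink_pos=crosslink)
    ref.add_region(Region("rRNA_18S", "site", site.start, site.end))
    return ref, [site], duplex_truth, cfg, background_weight
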