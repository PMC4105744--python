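# Methods

## Scope and coordinate conventions

The pipeline operates on a *transcript set*: a handful of named RNAs (a
pre-rRNA-like reference, snoRNAs, controls) with named regions such as
expansion-segment helices.  All user-facing coordinates are 1-based
inclusive; the only 0-based half-open output is bedGraph, where the format
requires it.  Input sequences are normalized to A/C/G/U (T→U, lowercase
uppercased); ambiguity codes are rejected because the intended targets
(rDNA, snoRNAs) are unambiguous.

## Duplex energy model

Intermolecular nearest-neighbor model in the RNAduplex/RNAhybrid
tradition.  A structure is a set of pairs (i on x, j on y), strictly
increasing in i and strictly decreasing in j (antiparallel, non-crossing),
drawn from the six canonical pairs AU, UA, GC, CG, GU, UG.  Its free
energy is

    dG = duplex_init + sum(step terms) + terminal penalties

where a step between consecutive pairs is either a stack (tabulated
ΔG°₃₇) or an interior loop/bulge with `a`,`b` unpaired nucleotides per
side (each ≤ `max_loop` = 15), costing `loop_base + loop_slope·(a+b)`
(defaults 2.0 and 0.5 kcal/mol).  Each helix end closed by AU/UA/GU/UG
pays `terminal_au` = 0.45; a single-pair duplex has two ends and pays it
twice.  `duplex_init` = 4.09.  There are no dangling-end or coaxial terms,
and no intramolecular pairs by construction.

Parameters ship as an editable TSV (`craclash/data/duplex_energies.tsv`).
The Watson–Crick stack values are the Turner-2004 set; wobble-containing
stacks use Turner-style values; the table is closed under the
reverse-complement symmetry stack(p1→p2) = stack(rev p2 → rev p1), which a
test asserts.  The affine loop model is a deliberate simplification of the
tabulated loop energies real folders use: published duplex tools differ
between parameter versions anyway, so absolute energies here are
model-relative, while orderings and planted-site recoveries are robust.

Numerically, energies are integer centi-kcal/mol throughout, so the fast
scanning kernel (numba), the traceback dynamic program (pure Python) and
the exhaustive oracle agree *exactly*, with no float-tolerance in tests.
Ties are broken toward more pairs, then the lexicographically smallest
pair list, making every output deterministic.  The exhaustive oracle
enumerates all antiparallel non-crossing pairings (guarded to
len(x)·len(y) ≤ 100) and is the independent ground truth for the DP.

## Window scan and site merging

Both RNAs are tiled with 20-nt windows every 5 nt (window 20, overlap 15);
one trailing window is anchored at the sequence end when the tiling does
not reach it, and sequences shorter than one window are taken whole.
Every query-window × target-window pair with duplex MFE ≤ −20 kcal/mol is
significant.  Significant window pairs overlapping on both axes merge
transitively into predicted sites.

A merged site reports the minimum MFE among members and the paired span of
the *best-energy window chain*: the structure of the minimum-energy
member, extended by stack-contiguous pairs contributed by overlapping
members.  Two alternatives were considered and rejected: the plain union
of paired positions over all members is inflated by marginal windows that
clear the cutoff only by combining part of the real helix with an
incidental second mini-helix elsewhere in the window; the span of the
single best member alone can be too short, because with a 5-nt step no
single window need fully cover a site longer than `window − step`.  The
chain rule reports a 19-nt planted helix as exactly 19 nt regardless of
its phase relative to the tiling.  Its cost: an interaction whose internal
loops fall outside the best window's reach is reported at the best
window's extent plus contiguous extensions only — long multi-loop
interactions may be reported piecewise.

## Read simulation (what it emulates, and what not)

The generator emulates the two read classes of a CRAC/CLASH library over
planted ground truth:

- **CRAC reads**: starts drawn from a weighted mixture of binding-site
  intervals (uniform within each) plus a uniform background component;
  lengths uniform in `read_length_range` (default 20–30 nt), truncated and
  flagged at the RNA 3′ end.  A read covering a planted cross-link carries
  a mutation there with probability `crosslink_rate` (default 0.3); a
  `deletion_fraction` (default 0.2) of those are single-nucleotide
  deletions, the rest substitutions to a random different base.  Illumina
  noise is a per-base substitution at `background_error_rate` (default
  0.001).  Reads are single-end and strand-matched (CRAC linkers preserve
  orientation); qualities are constant and never used.
- **Chimeric reads**: for each planted duplex, one fragment overlapping
  the query arm and one overlapping the target arm are concatenated
  5′→3′ in random order; fragments fully contain their arm when long
  enough, otherwise lie inside it.  Truth records both arm loci and the
  junction in *leftmost canonical form*: when the last base of the first
  arm equals the reference base preceding the second arm, the junction is
  not identifiable from the read, so truth stores the leftmost equivalent
  split — the same form the detector reports.

Ground-truth integrity choices: `plant_interaction` writes the reverse
complement of the target interval into the query (with an exact
`round(gu_fraction·length)` count of seeded G:U wobbles) and sets 2
flanking nucleotides on each side of both intervals to A, so the planted
helix cannot be extended by chance flank complementarity and the recorded
duplex length is exact.  `standard_scenario` places the cross-link at the
position nearest the site center whose base differs from both neighbors:
a deletion inside a homopolymer run cannot be attributed to one position
(alignment left-normalizes it), which would make cross-link localization
ill-posed rather than hard.

Not modeled: PCR duplicates, adapters (trimming is a downstream length
filter), paired-end reads, ligation-noise background for chimeras,
quality-dependent errors.  Passing tests therefore demonstrate the
*computational* recovery properties of the pipeline under its own
generative model, not robustness to every artifact of real libraries.

## Read mapping

Exhaustive ungapped end-to-end placement over every RNA (numpy sliding
windows), plus placements with one single-nucleotide reference deletion —
the cross-link signature; at most one per read, since cross-link-induced
deletions are single events.  Score = matches − 2·mismatches −
2·deletions, mismatch budget 2, minimum length 17 nt.  The unique
best-scoring placement is kept; ties at the same start prefer the
ungapped placement, then the smallest (leftmost) deletion offset; ties
across distinct loci discard the read as multi-mapped (no fractional
assignment).  Deletions at the first read position are inherently
invisible (the read is then a perfect shorter substring), which removes
about `deletion_fraction / read_length` of cross-link mutations — a ~0.4%
absolute downward bias on the rate estimate, well inside the binomial
noise at the simulated depths.

## Profiles, peaks, enrichment

Every covered nucleotide of every alignment counts one hit; tracks are
scaled to hits per million *mapped* reads by default (the denominator is
configurable to the raw library size, as the two conventions both occur in
practice).  Mutation counts add substitutions and deletions at their
reference positions; the rate divides by per-position coverage.  Peaks
are maximal runs of nucleotides ≥ `threshold_fraction` (default 0.05) of
the highest per-nucleotide value within a configurable scope (the
pre-rRNA by default); relative heights are reported against that maximum,
so peak intervals and relative heights are invariant under uniform
scaling.  A peak is control-flagged when ≥ 50% of its nucleotides fall
inside the union of peaks from an untagged-control sample.  snoRNA
enrichment is reads per million mapped per snoRNA-class RNA, scaled to
the maximum across snoRNAs.

## Chimera detection

Reads with any full-length placement (≤2 mismatches, deletion allowed)
are never chimeras.  Remaining reads are split at every junction leaving
both arms ≥ `min_arm_length` = 17 (the conventional short-read length
floor); each arm is placed independently (ungapped, ≤1 mismatch, unique
best required).  Arms must hit different RNAs or the same RNA with a gap
> 30 nt (intramolecular long-range hybrids are biologically meaningful).
Among valid junctions, the one maximizing matched bases wins; ties go to
the smallest junction, the same canonicalization the simulator's truth
uses.  Note one consequence of the per-arm mismatch budget: a read whose
true first arm is one base short of the floor can still be called, with
the boundary base absorbed as a mismatch and the junction off by one —
the detector reports the best *explanation* of the read, not inaccessible
generative history.  Each hybrid is annotated with the duplex MFE of its
arms' reference sequences (± an optional flank, truncated at RNA bounds).

## Interaction map

Predictions and hybrids are points/rectangles on the (target × query)
plane.  Hybrids with identical arm loci collapse into one item with an
evidence count so read depth does not distort clustering.  Single-linkage
clustering links two items when the interval gap is ≤ `linkage_distance`
(default 30 nt, conservative relative to typical site spacing) on *both*
axes; with distance 0 this reduces to the transitive closure of two-axis
overlap.  Clusters are labeled C1, C2, … by target-axis start and are
invariant under input order.  A cluster is *supported* when it contains a
prediction and a hybrid that mutually overlap by ≥1 nt on both axes.  The
report annotates clusters with overlapping named regions and emits an
edge list (protein→region edges from CRAC peaks, region→region edges from
hybrids and predictions) for downstream network drawing; visualization
itself is out of scope.

## Problem sizes and determinism

Default verification sizes: transcript sets of ~2–3 kb total, libraries
of 10,000 reads, 500-nt RNA pairs for scan recovery (20 seeds), 1000
chimeras against 9000 contiguous reads.  All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; a fixed seed
reproduces byte-identical FASTQ output.  The duplex scan's hot loop is a
numba kernel (integer DP, ~9,400 window pairs per 500×500 scan in about a
second after JIT warm-up); everything else is numpy or plain Python.

## Known limitations

- The affine loop model under-penalizes single bulges relative to
  tabulated parameters; absolute MFEs are not comparable across parameter
  versions of published folders (orderings and recovery behavior are).
- The mapper is exact but O(reads × reference); it is built for
  transcript sets, not genomes.
- Two-arm chimeras only; three-fragment concatemers are dropped.
- No statistical significance on peaks or clusters — thresholds are
  descriptive (fraction-of-maximum, energy cutoff), as is conventional
  for this analysis type.
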