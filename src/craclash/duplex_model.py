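"""Intermolecular RNA-RNA duplex minimum free energy and windowed scanning.

The model is a nearest-neighbor duplex model in the RNAduplex/RNAhybrid
tradition: two RNAs pair antiparallel without crossing, stacking steps
contribute tabulated free energies, interior loops/bulges pay an affine
penalty, a duplex pays one initiation term and each helix end closed by an
AU or GU pair pays a terminal penalty.  Intramolecular structure is excluded
by construction.  Energies are handled internally as integer centi-kcal/mol
so that the fast scanning kernel, the traceback dynamic program and the
exhaustive oracle agree exactly.

The window scan fragments both RNAs into short overlapping windows
(20 nt with a 15 nt overlap by default), folds every window pair and keeps
pairs at or below a stability cutoff (-20 kcal/mol by default); overlapping
significant window pairs are merged into predicted interaction sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

INF = np.int32(2**30)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")
# pair index table over (x base, y base); -1 = not pairable
PAIR_IDX = np.full((4, 4), -1, dtype=np.int8)
for _k, _p in enumerate(_PAIRS):
    PAIR_IDX[_BASE_CODE[_p[0]], _BASE_CODE[_p[1]]] = _k

_DEFAULT_TABLE = Path(__file__).parent / "data" / "duplex_energies.tsv"


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/U string as an int8 array (A=0, C=1, G=2, U=3)."""
    try:
        return np.array([_BASE_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - callers normalize first
        raise ValueError(f"non-ACGU character {exc.args[0]!r}") from exc


@dataclass
class EnergyModel:
    """Nearest-neighbor duplex parameters (kcal/mol at 37 C).

    ``stack[(p1, p2)]`` is the stacking free energy of the step from pair
    ``p1 = x_i + y_j`` to ``p2 = x_{i+1} + y_{j-1}``; ``loop_cost(a, b)``
    with ``a + b >= 1`` unpaired nucleotides is ``loop_base +
    loop_slope * (a + b)``; ``terminal_au`` is paid once per helix end
    closed by AU, UA, GU or UG (a single-pair duplex has two ends).
    """

    stack: dict[tuple[str, str], float]
    duplex_init: float = 4.09
    terminal_au: float = 0.45
    loop_base: float = 2.00
    loop_slope: float = 0.50
    max_loop: int = 15

    # integer (centi-kcal) views used by the DP kernels
    _stack_int: np.ndarray = field(init=False, repr=False)
    _term_int: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for p1 in _PAIRS:
            for p2 in _PAIRS:
                if (p1, p2) not in self.stack:
                    raise ValueError(f"missing stack entry {p1}->{p2}")
        if self.duplex_init < 0:
            raise ValueError("duplex_init must be >= 0")
        if self.loop_base < 0 or self.loop_slope < 0:
            raise ValueError("loop costs must be nonnegative")
        self._stack_int = np.zeros((6, 6), dtype=np.int32)
        for i, p1 in enumerate(_PAIRS):
            for j, p2 in enumerate(_PAIRS):
                self._stack_int[i, j] = _c(self.stack[(p1, p2)])
        # AU, UA, GU, UG pay the terminal penalty; GC, CG do not
        self._term_int = np.array(
            [0 if p in ("GC", "CG") else _c(self.terminal_au) for p in _PAIRS],
            dtype=np.int32,
        )

    def loop_cost(self, a: int, b: int) -> float:
        """Penalty for an interior loop/bulge with a,b unpaired nts per side."""
        if a == 0 and b == 0:
            raise ValueError("a=b=0 is a stack, not a loop")
        if a < 0 or b < 0 or a > self.max_loop or b > self.max_loop:
            raise ValueError(f"loop size ({a},{b}) outside [0,{self.max_loop}]")
        return self.loop_base + self.loop_slope * (a + b)

    @classmethod
    def from_table(cls, path: str | Path | None = None) -> "EnergyModel":
        """Load parameters from the TSV table shipped with the package."""
        path = Path(path) if path is not None else _DEFAULT_TABLE
        stack: dict[tuple[str, str], float] = {}
        scalars: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("param\t"):
                    continue
                kind, k1, k2, value = line.split("\t")
                if kind == "stack":
                    stack[(k1, k2)] = float(value)
                else:
                    scalars[kind] = float(value)
        return cls(
            stack=stack,
            duplex_init=scalars.get("duplex_init", 4.09),
            terminal_au=scalars.get("terminal_au", 0.45),
            loop_base=scalars.get("loop_base", 2.00),
            loop_slope=scalars.get("loop_slope", 0.50),
            max_loop=int(scalars.get("max_loop", 15)),
        )


def _c(kcal: float) -> int:
    """kcal/mol -> integer centi-kcal/mol."""
    return int(round(kcal * 100))


_DEFAULT_MODEL: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = EnergyModel.from_table()
    return _DEFAULT_MODEL


@dataclass
class DuplexResult:
    """A duplex structure: energy in kcal/mol and 1-based pair list.

    ``pairs`` is strictly increasing in i (on x) and strictly decreasing in
    j (on y): the two strands run antiparallel and pairs do not cross.
    ``energy is None`` is the no-duplex sentinel (no allowed pair exists).
    """

    energy: float | None
    pairs: list[tuple[int, int]]

    @property
    def is_duplex(self) -> bool:
        return self.energy is not None

    def paired_span_x(self) -> tuple[int, int]:
        return (self.pairs[0][0], self.pairs[-1][0])

    def paired_span_y(self) -> tuple[int, int]:
        return (self.pairs[-1][1], self.pairs[0][1])


NO_DUPLEX = DuplexResult(energy=None, pairs=[])


def score_pairs(x: str, y: str, pairs: Sequence[tuple[int, int]],
                m: EnergyModel | None = None) -> float:
    """Recompute the energy of a pair list; validates the structure.

    This is the single scoring function shared by the dynamic program and
    the exhaustive oracle, and the arbiter for the energy-recomputation
    invariant: every emitted DuplexResult must reproduce its energy here.
    """
    m = m or default_model()
    if not pairs:
        raise ValueError("empty pair list has no duplex energy")
    e = _score_pairs_int(x, y, pairs, m)
    return e / 100.0


def _score_pairs_int(x: str, y: str, pairs: Sequence[tuple[int, int]],
                     m: EnergyModel) -> int:
    def pair_name(i: int, j: int) -> str:
        if not (1 <= i <= len(x) and 1 <= j <= len(y)):
            raise ValueError(f"pair ({i},{j}) out of bounds")
        p = x[i - 1] + y[j - 1]
        if p not in _PAIRS:
            raise ValueError(f"({i},{j}) = {p} is not an allowed pair")
        return p

    e = _c(m.duplex_init)
    first = pair_name(*pairs[0])
    last = pair_name(*pairs[-1])
    e += m._term_int[_PAIRS.index(first)] + m._term_int[_PAIRS.index(last)]
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i2 > i1 and j2 < j1):
            raise ValueError("pairs must increase in i and decrease in j")
        a, b = i2 - i1 - 1, j1 - j2 - 1
        p1, p2 = pair_name(i1, j1), pair_name(i2, j2)
        if a == 0 and b == 0:
            e += m._stack_int[_PAIRS.index(p1), _PAIRS.index(p2)]
        else:
            e += _c(m.loop_cost(a, b))
    return int(e)


def duplex_mfe(x: str, y: str, m: EnergyModel | None = None) -> DuplexResult:
    """Minimum free energy intermolecular duplex between two RNAs.

    Dynamic program over "best duplex whose 3'-most pair on x is (i, j)",
    extended by stacks or affine loops.  Ties are broken toward more pairs,
    then the lexicographically smallest pair list, which makes the output
    deterministic.  Returns the no-duplex sentinel when no allowed pair
    exists between the sequences.
    """
    m = m or default_model()
    n, mm = len(x), len(y)
    if n == 0 or mm == 0:
        raise ValueError("sequences must be nonempty")
    xc, yc = encode(x), encode(y)
    init = _c(m.duplex_init)
    max_loop = m.max_loop

    # best[(i, j)] = (energy incl. init + 5'-terminal penalty, -npairs, pairs)
    best: dict[tuple[int, int], tuple[int, int, tuple[tuple[int, int], ...]]] = {}
    answer: tuple[int, int, tuple[tuple[int, int], ...]] | None = None
    for i in range(n):
        for j in range(mm - 1, -1, -1):
            p = PAIR_IDX[xc[i], yc[j]]
            if p < 0:
                continue
            term_p = int(m._term_int[p])
            cell = (init + term_p, -1, ((i + 1, j + 1),))
            for i2 in range(max(0, i - 1 - max_loop), i):
                for j2 in range(j + 1, min(mm, j + 2 + max_loop)):
                    prev = best.get((i2, j2))
                    if prev is None:
                        continue
                    a, b = i - i2 - 1, j2 - j - 1
                    if a == 0 and b == 0:
                        q = PAIR_IDX[xc[i2], yc[j2]]
                        cost = int(m._stack_int[q, p])
                    else:
                        cost = _c(m.loop_cost(a, b))
                    cand = (prev[0] + cost, prev[1] - 1, prev[2] + ((i + 1, j + 1),))
                    if cand < cell:
                        cell = cand
            best[(i, j)] = cell
            final = (cell[0] + term_p, cell[1], cell[2])
            if answer is None or final < answer:
                answer = final
    if answer is None:
        return DuplexResult(energy=None, pairs=[])
    return DuplexResult(energy=answer[0] / 100.0, pairs=list(answer[2]))


def duplex_bruteforce(x: str, y: str, m: EnergyModel | None = None,
                      max_area: int = 100) -> DuplexResult:
    """Exhaustive enumeration oracle for duplex_mfe on tiny sequences.

    Enumerates every antiparallel non-crossing pairing with >= 1 pair and
    per-side loop sizes <= max_loop, scores each with score_pairs, and
    returns the minimum under the same tie-break rule as the DP.
    """
    m = m or default_model()
    n, mm = len(x), len(y)
    if n * mm > max_area:
        raise ValueError(f"brute force guard: len(x)*len(y) = {n * mm} > {max_area}")
    best: tuple[int, int, tuple[tuple[int, int], ...]] | None = None
    for k in range(1, min(n, mm) + 1):
        for xi in itertools.combinations(range(1, n + 1), k):
            for yj in itertools.combinations(range(1, mm + 1), k):
                pairs = tuple(zip(xi, reversed(yj)))
                ok = all(x[i - 1] + y[j - 1] in _PAIRS for i, j in pairs)
                if not ok:
                    continue
                if any(
                    (i2 - i1 - 1 > m.max_loop) or (j1 - j2 - 1 > m.max_loop)
                    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:])
                ):
                    continue
                e = _score_pairs_int(x, y, pairs, m)
                cand = (e, -k, pairs)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return DuplexResult(energy=None, pairs=[])
    return DuplexResult(energy=best[0] / 100.0, pairs=list(best[2]))


@njit(cache=True)
def _mfe_energy_kernel(xc, yc, pair_idx, stack_int, term_int, init_int,
                       loop_base_int, loop_slope_int, max_loop):  # pragma: no cover
    n = xc.shape[0]
    mm = yc.shape[0]
    best = np.full((n, mm), INF, dtype=np.int64)
    ans = np.int64(INF)
    for i in range(n):
        for j in range(mm - 1, -1, -1):
            p = pair_idx[xc[i], yc[j]]
            if p < 0:
                continue
            cell = np.int64(init_int + term_int[p])
            i_lo = i - 1 - max_loop
            if i_lo < 0:
                i_lo = 0
            j_hi = j + 1 + max_loop
            if j_hi > mm - 1:
                j_hi = mm - 1
            for i2 in range(i_lo, i):
                for j2 in range(j + 1, j_hi + 1):
                    prev = best[i2, j2]
                    if prev >= INF:
                        continue
                    a = i - i2 - 1
                    b = j2 - j - 1
                    if a == 0 and b == 0:
                        q = pair_idx[xc[i2], yc[j2]]
                        cost = np.int64(stack_int[q, p])
                    else:
                        cost = np.int64(loop_base_int + loop_slope_int * (a + b))
                    cand = prev + cost
                    if cand < cell:
                        cell = cand
            best[i, j] = cell
            final = cell + term_int[p]
            if final < ans:
                ans = final
    return ans


def duplex_mfe_energy(x: str | np.ndarray, y: str | np.ndarray,
                      m: EnergyModel | None = None) -> float | None:
    """Energy-only fast path of duplex_mfe (identical integer recurrence)."""
    m = m or default_model()
    xc = encode(x) if isinstance(x, str) else x
    yc = encode(y) if isinstance(y, str) else y
    e = _mfe_energy_kernel(
        xc, yc, PAIR_IDX, m._stack_int, m._term_int,
        _c(m.duplex_init), _c(m.loop_base), _c(m.loop_slope), m.max_loop,
    )
    return None if e >= INF else e / 100.0


def tile_windows(length: int, window: int = 20, overlap: int = 15) -> list[tuple[int, int]]:
    """1-based inclusive window tiling with a trailing end-anchored window.

    Windows of size ``window`` start every ``window - overlap`` nucleotides;
    if the last regular window does not reach the sequence end, one extra
    window anchored at the end is added.  Sequences shorter than ``window``
    yield a single whole-sequence window.
    """
    if not (window > overlap >= 0):
        raise ValueError("require window > overlap >= 0")
    if length < 1:
        raise ValueError("length must be >= 1")
    if length <= window:
        return [(1, length)]
    step = window - overlap
    starts = list(range(1, length - window + 2, step))
    if starts[-1] + window - 1 < length:
        starts.append(length - window + 1)
    return [(s, s + window - 1) for s in starts]


@dataclass
class WindowHit:
    """One significant query-window x target-window duplex."""

    q_window: tuple[int, int]
    t_window: tuple[int, int]
    result: DuplexResult  # pairs in global 1-based coordinates

    @property
    def mfe(self) -> float:
        assert self.result.energy is not None
        return self.result.energy


@dataclass
class PredictedSite:
    """A merged interaction site from overlapping significant windows.

    The reported interval on each RNA is the paired span: the smallest
    interval containing every base-paired nucleotide contributed by the
    merged windows (unpaired window overhang is excluded, so a 19-nt
    interaction inside 20-nt windows is reported as 19 nt).
    """

    query_rna: str
    q_start: int
    q_end: int
    target_rna: str
    t_start: int
    t_end: int
    mfe: float
    n_windows: int


def window_scan(query: str, target: str, m: EnergyModel | None = None,
                window: int = 20, overlap: int = 15, cutoff: float = -20.0,
                fragment: str = "both") -> list[WindowHit]:
    """Fold every window pair of two RNAs; keep pairs with MFE <= cutoff.

    ``fragment`` selects which RNA is fragmented: "both" (default), "query"
    (the target is taken whole) or "target".
    """
    m = m or default_model()
    if fragment not in ("both", "query", "target"):
        raise ValueError("fragment must be 'both', 'query' or 'target'")
    qwins = (tile_windows(len(query), window, overlap)
             if fragment in ("both", "query") else [(1, len(query))])
    twins = (tile_windows(len(target), window, overlap)
             if fragment in ("both", "target") else [(1, len(target))])
    qc, tc = encode(query), encode(target)
    cutoff_int = _c(cutoff)
    hits: list[WindowHit] = []
    for qs, qe in qwins:
        xw = qc[qs - 1 : qe]
        for ts, te in twins:
            yw = tc[ts - 1 : te]
            e = _mfe_energy_kernel(
                xw, yw, PAIR_IDX, m._stack_int, m._term_int,
                _c(m.duplex_init), _c(m.loop_base), _c(m.loop_slope), m.max_loop,
            )
            if e >= INF or e > cutoff_int:
                continue
            res = duplex_mfe(query[qs - 1 : qe], target[ts - 1 : te], m)
            assert res.energy is not None and _c(res.energy) == e
            global_pairs = [(qs + i - 1, ts + j - 1) for i, j in res.pairs]
            hits.append(WindowHit((qs, qe), (ts, te),
                                  DuplexResult(res.energy, global_pairs)))
    return hits


def merge_windows(hits: Sequence[WindowHit], query_rna: str = "query",
                  target_rna: str = "target") -> list[PredictedSite]:
    """Merge window hits that overlap on both the query and target axes.

    Overlapping hits are merged transitively (single linkage on window
    intervals).  Each merged site reports the minimum MFE among its members
    and the paired span of the best-energy window chain: the structure of
    the minimum-energy member, completed by stack-contiguous pairs
    contributed by overlapping member windows (a helix reaching beyond one
    window is thereby reported full-length, while incidental extra helices
    recruited by marginal windows do not stretch the span).
    """
    n = len(hits)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    def overlaps(u: tuple[int, int], v: tuple[int, int]) -> bool:
        return not (u[1] < v[0] or v[1] < u[0])

    for a in range(n):
        for b in range(a + 1, n):
            if overlaps(hits[a].q_window, hits[b].q_window) and overlaps(
                hits[a].t_window, hits[b].t_window
            ):
                union(a, b)

    groups: dict[int, list[WindowHit]] = {}
    for idx in range(n):
        groups.setdefault(find(idx), []).append(hits[idx])

    sites = []
    for members in groups.values():
        best = min(members, key=lambda h: (h.mfe, h.q_window, h.t_window))
        chain = sorted(best.result.pairs)
        pool = {p for h in members for p in h.result.pairs}
        # complete the best structure's helix across overlapping windows
        while (chain[0][0] - 1, chain[0][1] + 1) in pool:
            chain.insert(0, (chain[0][0] - 1, chain[0][1] + 1))
        while (chain[-1][0] + 1, chain[-1][1] - 1) in pool:
            chain.append((chain[-1][0] + 1, chain[-1][1] - 1))
        sites.append(
            PredictedSite(
                query_rna=query_rna,
                q_start=chain[0][0],
                q_end=chain[-1][0],
                target_rna=target_rna,
                t_start=chain[-1][1],
                t_end=chain[0][1],
                mfe=min(h.mfe for h in members),
                n_windows=len(members),
            )
        )
    sites.sort(key=lambda s: (s.t_start, s.q_start))
    return sites
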