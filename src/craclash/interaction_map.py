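"""Integration of predicted sites and CLASH hybrids on the 2D plane.

Predicted base-pairing sites and experimentally observed hybrids live on
the same (target position x query position) plane.  A prediction is
"supported" when a hybrid overlaps it on both axes; co-located items are
grouped by single-linkage clustering with a two-axis gap rule, and the
final report annotates clusters with named reference regions and emits an
interaction-network edge list.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .clash_chimeras import ChimericRead
from .crac_profile import Peak
from .duplex_model import PredictedSite
from .reference_io import ReferenceSet, regions_overlapping


@dataclass(frozen=True)
class InteractionItem:
    """One item on the interaction plane: a prediction or a hybrid."""

    source: str  # "predicted" | "hybrid"
    query_rna: str
    q_start: int
    q_end: int
    target_rna: str
    t_start: int
    t_end: int
    mfe: float | None = None
    evidence: int = 1

    def __post_init__(self) -> None:
        if self.source not in ("predicted", "hybrid"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "hybrid" and self.evidence < 1:
            raise ValueError("hybrid items need evidence >= 1")


@dataclass
class InteractionCluster:
    """Items co-located on both axes; supported when a prediction and a
    hybrid inside the cluster mutually overlap on both axes."""

    cluster_id: str
    members: list[InteractionItem]
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    supported: bool


def items_from_predictions(sites: Sequence[PredictedSite]) -> list[InteractionItem]:
    return [
        InteractionItem("predicted", s.query_rna, s.q_start, s.q_end,
                        s.target_rna, s.t_start, s.t_end, mfe=s.mfe)
        for s in sites
    ]


def items_from_hybrids(chimeras: Sequence[ChimericRead], query_rna: str,
                       target_rna: str) -> list[InteractionItem]:
    """Orient hybrids onto the (query, target) axes and collapse duplicates.

    Only chimeras with one arm on each of the two RNAs are kept; hybrids
    with identical arm loci collapse into one item with an evidence count,
    so read depth does not distort clustering.
    """
    collapsed: dict[tuple[int, int, int, int], list[ChimericRead]] = {}
    for c in chimeras:
        arms = {c.arm_a.rna_id: c.arm_a, c.arm_b.rna_id: c.arm_b}
        if set(arms) != {query_rna, target_rna}:
            continue
        q, t = arms[query_rna], arms[target_rna]
        collapsed.setdefault((q.start, q.end, t.start, t.end), []).append(c)
    items = []
    for (qs, qe, ts, te), group in sorted(collapsed.items()):
        mfes = [c.hybrid_mfe for c in group if c.hybrid_mfe is not None]
        items.append(InteractionItem("hybrid", query_rna, qs, qe,
                                     target_rna, ts, te,
                                     mfe=min(mfes) if mfes else None,
                                     evidence=len(group)))
    return items


def _overlap_len(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def support_overlap(predicted: Sequence[InteractionItem],
                    hybrids: Sequence[InteractionItem],
                    min_overlap: int = 1) -> list[tuple[InteractionItem, InteractionItem]]:
    """(prediction, hybrid) pairs overlapping >= min_overlap nt on BOTH axes."""
    pairs = []
    for p in predicted:
        for h in hybrids:
            if p.query_rna != h.query_rna or p.target_rna != h.target_rna:
                continue
            if (_overlap_len(p.q_start, p.q_end, h.q_start, h.q_end) >= min_overlap
                    and _overlap_len(p.t_start, p.t_end, h.t_start, h.t_end) >= min_overlap):
                pairs.append((p, h))
    return pairs


def cluster_interactions(items: Sequence[InteractionItem],
                         linkage_distance: int = 30) -> list[InteractionCluster]:
    """Single-linkage clustering with a two-axis (Chebyshev-style) gap rule.

    Two items link iff the gap between their intervals is
    <= linkage_distance on the query axis AND on the target axis (gap 0
    when overlapping); linkage is transitive.  Clusters are labeled C1, C2,
    ... by target-axis start and are invariant under input order.
    """
    items = sorted(items, key=lambda it: (it.target_rna, it.query_rna,
                                          it.t_start, it.t_end,
                                          it.q_start, it.q_end, it.source))
    n = len(items)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def gap(s1: int, e1: int, s2: int, e2: int) -> int:
        return max(0, max(s1, s2) - min(e1, e2) - 1)

    for a in range(n):
        for b in range(a + 1, n):
            ia, ib = items[a], items[b]
            if ia.query_rna != ib.query_rna or ia.target_rna != ib.target_rna:
                continue
            if (gap(ia.q_start, ia.q_end, ib.q_start, ib.q_end) <= linkage_distance
                    and gap(ia.t_start, ia.t_end, ib.t_start, ib.t_end) <= linkage_distance):
                parent[find(b)] = find(a)

    groups: dict[int, list[InteractionItem]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(items[k])

    clusters = []
    for members in groups.values():
        preds = [m for m in members if m.source == "predicted"]
        hybs = [m for m in members if m.source == "hybrid"]
        supported = bool(support_overlap(preds, hybs))
        clusters.append(InteractionCluster(
            cluster_id="",  # assigned after sorting
            members=members,
            q_start=min(m.q_start for m in members),
            q_end=max(m.q_end for m in members),
            t_start=min(m.t_start for m in members),
            t_end=max(m.t_end for m in members),
            supported=supported,
        ))
    clusters.sort(key=lambda c: (c.t_start, c.q_start))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"C{i}"
    return clusters


def build_interaction_report(clusters: Sequence[InteractionCluster],
                             peaks: Sequence[Peak], ref: ReferenceSet,
                             protein: str = "protein"):
    """Cluster table plus interaction-network edge list as DataFrames.

    Network nodes are ``rna_id:region_name`` (or the bare rna_id when no
    named region overlaps) plus one protein node; edges are typed
    crac_peak (protein-RNA contact), clash_hybrid or predicted_site
    (RNA-RNA interaction), with evidence counts.
    """
    import pandas as pd

    def region_label(rna_id: str, start: int, end: int) -> str:
        names = [r.name for r in regions_overlapping(ref, rna_id, start, end)]
        return f"{rna_id}:{','.join(names)}" if names else rna_id

    rows = []
    for c in clusters:
        if c.members:
            q_rna = c.members[0].query_rna
            t_rna = c.members[0].target_rna
        else:  # pragma: no cover - clusters always have members
            q_rna = t_rna = ""
        rows.append({
            "cluster_id": c.cluster_id,
            "query_rna": q_rna, "q_start": c.q_start, "q_end": c.q_end,
            "target_rna": t_rna, "t_start": c.t_start, "t_end": c.t_end,
            "n_members": len(c.members),
            "n_predicted": sum(m.source == "predicted" for m in c.members),
            "n_hybrids": sum(m.source == "hybrid" for m in c.members),
            "evidence": sum(m.evidence for m in c.members if m.source == "hybrid"),
            "supported": c.supported,
            "query_regions": ",".join(
                r.name for r in regions_overlapping(ref, q_rna, c.q_start, c.q_end)),
            "target_regions": ",".join(
                r.name for r in regions_overlapping(ref, t_rna, c.t_start, c.t_end)),
        })
    cluster_df = pd.DataFrame(rows, columns=[
        "cluster_id", "query_rna", "q_start", "q_end", "target_rna", "t_start",
        "t_end", "n_members", "n_predicted", "n_hybrids", "evidence",
        "supported", "query_regions", "target_regions"])

    edges = []
    for p in peaks:
        edges.append({"node_a": protein,
                      "node_b": region_label(p.rna_id, p.start, p.end),
                      "edge_type": "crac_peak", "evidence": 1})
    for c in clusters:
        for m in c.members:
            edges.append({
                "node_a": region_label(m.query_rna, m.q_start, m.q_end),
                "node_b": region_label(m.target_rna, m.t_start, m.t_end),
                "edge_type": "clash_hybrid" if m.source == "hybrid" else "predicted_site",
                "evidence": m.evidence,
            })
    edge_df = (pd.DataFrame(edges, columns=["node_a", "node_b", "edge_type",
                                            "evidence"])
               .groupby(["node_a", "node_b", "edge_type"], as_index=False)["evidence"]
               .sum())
    return cluster_df, edge_df


def write_clusters_tsv(cluster_df, path: str | Path) -> None:
    cluster_df.to_csv(path, sep="\t", index=False)


def write_network_tsv(edge_df, path: str | Path) -> None:
    edge_df.to_csv(path, sep="\t", index=False)


def write_sites_tsv(sites: Sequence[PredictedSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["query_rna", "q_start", "q_end", "target_rna", "t_start",
                    "t_end", "mfe_kcal_mol", "n_windows"])
        for s in sites:
            w.writerow([s.query_rna, s.q_start, s.q_end, s.target_rna,
                        s.t_start, s.t_end, f"{s.mfe:.2f}", s.n_windows])


def read_sites_tsv(path: str | Path) -> list[PredictedSite]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(PredictedSite(
                query_rna=row["query_rna"], q_start=int(row["q_start"]),
                q_end=int(row["q_end"]), target_rna=row["target_rna"],
                t_start=int(row["t_start"]), t_end=int(row["t_end"]),
                mfe=float(row["mfe_kcal_mol"]), n_windows=int(row["n_windows"])))
    return out
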