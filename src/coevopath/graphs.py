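"""Community structure and centrality of residue networks.

Communities come from the Girvan–Newman procedure: edges of highest
weighted edge-betweenness are removed one at a time and the partition of
maximal weighted modularity seen along the removal sequence is returned.
Betweenness centrality treats edge weights as conductances (shortest-path
length = 1/weight).  Partition comparison intersects the communities
containing an anchor residue in two partitions, restricted to a residue
window, which is how a sequence-space module is matched against a
structure-space module around a mutation site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

__all__ = [
    "CommunityPartition",
    "girvan_newman",
    "betweenness",
    "compare_partitions",
    "extract_stretch",
    "Mutation",
]


@dataclass(frozen=True)
class CommunityPartition:
    """Disjoint node communities covering a network, with their modularity."""

    communities: tuple[frozenset, ...]
    modularity: float
    provenance: str = ""

    def __post_init__(self) -> None:
        nodes: set = set()
        for c in self.communities:
            if nodes & c:
                raise ValueError("communities overlap")
            nodes |= c
        if not -0.5 - 1e-12 <= self.modularity <= 1.0 + 1e-12:
            raise ValueError(f"modularity {self.modularity} out of range")

    @property
    def node_set(self) -> frozenset:
        return frozenset().union(*self.communities)

    def community_of(self, node: Hashable) -> frozenset:
        for c in self.communities:
            if node in c:
                return c
        raise KeyError(f"node {node!r} not covered by the partition")

    def as_sets(self) -> set[frozenset]:
        return set(self.communities)


def _add_lengths(g: nx.Graph) -> nx.Graph:
    h = g.copy()
    for u, v, data in h.edges(data=True):
        w = data.get("weight", 1.0)
        if w < 0 or not w < float("inf"):
            raise ValueError(f"edge ({u}, {v}) has invalid weight {w}")
        data["length"] = 1.0 / w if w > 0 else float("inf")
    return h


def _sorted_partition(g: nx.Graph) -> tuple[frozenset, ...]:
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: sorted(map(str, c)))
    return tuple(comps)


def girvan_newman(net: nx.Graph) -> CommunityPartition:
    """Best-modularity partition along the Girvan–Newman edge removals.

    At each step the edge of highest weighted edge-betweenness — shortest
    -path betweenness divided by the edge weight, the classic weighted
    generalization, so weak inter-community links fall first — is removed
    (ties broken by lexicographic edge order); every intermediate
    component partition, including the untouched network, is scored by
    weighted modularity and the best one is returned (earliest on ties).
    """
    if net.number_of_edges() == 0:
        raise ValueError("Girvan-Newman needs at least one edge")
    work = net.copy()
    best_partition = _sorted_partition(work)
    best_q = nx.community.modularity(net, best_partition, weight="weight")
    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work)
        eb = {
            e: v / work.edges[e].get("weight", 1.0) for e, v in eb.items()
        }
        top = max(eb.values())
        # deterministic: among ties prefer the lexicographically smallest edge
        ties = [e for e, v in eb.items() if v == top]
        edge = min(ties, key=_edge_key)
        work.remove_edge(*edge)
        partition = _sorted_partition(work)
        q = nx.community.modularity(net, partition, weight="weight")
        if q > best_q + 1e-12:
            best_q, best_partition = q, partition
    return CommunityPartition(
        communities=best_partition,
        modularity=best_q,
        provenance=net.graph.get("provenance", ""),
    )


def _edge_key(edge: tuple) -> tuple:
    u, v = sorted(map(str, edge))
    return (u, v)


def betweenness(net: nx.Graph) -> dict:
    """Normalized shortest-path betweenness with edge length = 1/weight."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    work = _add_lengths(net)
    return nx.betweenness_centrality(work, weight="length", normalized=True)


def compare_partitions(
    p1: CommunityPartition,
    p2: CommunityPartition,
    anchor: Hashable,
    focus_range: tuple[int, int] | None = None,
) -> tuple[frozenset, float]:
    """Intersect the anchor's communities of two partitions within a window.

    Returns the shared members of the two anchor communities restricted to
    the inclusive ``focus_range`` (residue numbers), together with the
    Jaccard index of the two full communities.
    """
    try:
        c1 = p1.community_of(anchor)
    except KeyError as exc:
        raise KeyError(f"anchor {anchor!r} absent from the first partition") from exc
    try:
        c2 = p2.community_of(anchor)
    except KeyError as exc:
        raise KeyError(f"anchor {anchor!r} absent from the second partition") from exc
    inter = c1 & c2
    union = c1 | c2
    jaccard = len(inter) / len(union) if union else 0.0
    if focus_range is not None:
        lo, hi = focus_range
        inter = frozenset(n for n in inter if lo <= n <= hi)
    return frozenset(inter), jaccard


@dataclass(frozen=True)
class Mutation:
    """A point mutation in standard nomenclature (e.g. E46K)."""

    position: int
    wild_type: str
    alternate: str

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        wt, alt = text[0].upper(), text[-1].upper()
        pos = int(text[1:-1])
        return cls(position=pos, wild_type=wt, alternate=alt)

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.alternate}"


def extract_stretch(
    seq: str,
    start: int = 40,
    end: int = 95,
    mutations: Sequence[Mutation | str] = (),
    seq_id: str = "stretch",
) -> SeqRecord:
    """Cut a 1-based inclusive residue stretch, applying point mutations first.

    Each mutation names its expected wild-type residue; a mismatch with
    the actual sequence raises, guarding against off-by-one mistakes.
    """
    n = len(seq)
    if not (1 <= start <= end <= n):
        raise ValueError(f"stretch {start}-{end} outside sequence of length {n}")
    residues = list(seq.upper())
    applied = []
    for mut in mutations:
        if isinstance(mut, str):
            mut = Mutation.parse(mut)
        if not (1 <= mut.position <= n):
            raise ValueError(f"mutation position {mut.position} outside sequence")
        actual = residues[mut.position - 1]
        if actual != mut.wild_type:
            raise ValueError(
                f"mutation {mut} expects {mut.wild_type} at position "
                f"{mut.position} but the sequence has {actual}"
            )
        residues[mut.position - 1] = mut.alternate
        applied.append(str(mut))
    stretch = "".join(residues[start - 1 : end])
    desc = f"residues {start}-{end}" + (f" mutations {','.join(applied)}" if applied else "")
    return SeqRecord(Seq(stretch), id=seq_id, description=desc)
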