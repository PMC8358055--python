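"""Pathway semantics: PPI/pathway filtering, Wang GO similarity, BMA
pathway graphs and PageRank ranking.

The Wang measure scores a Gene Ontology term T by propagating an S-value
down its ancestor DAG:

    S_T(T) = 1
    S_T(p) = max{ c_e * S_T(p') : p' a child of p inside T's DAG }

with a per-relation contribution factor c_e (0.8 for is-a, 0.6 for
part-of by default).  The semantic value SV(T) sums the S-values over the
ancestor set; two terms compare as

    SS_w(T, Q) = sum_{p in X_T ∩ X_Q} [S_T(p) + S_Q(p)] / [SV(T) + SV(Q)]

Term *sets* (the GO annotations pooled over a pathway's member proteins)
compare through the best-match average (BMA), and pathways become nodes
of a semantic graph whose BMA edge weights feed a weighted PageRank

    PR(n) = sum_{m adjacent to n} PR(m) * w_mn / W_m

(W_m = total incident weight of m), whose stationary distribution ranks
the pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CONTRIBUTION_FACTORS",
    "PPITable",
    "PathwayCatalog",
    "SValueMap",
    "filter_partners",
    "filter_pathways",
    "load_go_graph",
    "load_go_obo",
    "s_values",
    "semantic_value",
    "term_similarity",
    "bma_similarity",
    "build_semantic_graph",
    "pagerank",
]

logger = logging.getLogger(__name__)

#: Default per-relation semantic contribution factors of the Wang method.
CONTRIBUTION_FACTORS: Mapping[str, float] = {"is_a": 0.8, "part_of": 0.6}


@dataclass(frozen=True)
class PPITable:
    """Interaction partners of a query protein with combined scores in [0,1]."""

    query: str
    table: pd.DataFrame  # columns: partner, score

    def __post_init__(self) -> None:
        t = self.table
        if not {"partner", "score"} <= set(t.columns):
            raise ValueError("PPI table needs 'partner' and 'score' columns")
        if t["partner"].duplicated().any():
            raise ValueError("partner ids must be unique")
        if ((t["score"] < 0) | (t["score"] > 1)).any():
            raise ValueError("scores must lie in [0, 1]")

    @classmethod
    def from_tsv(cls, path: str | Path, query: str) -> "PPITable":
        return cls(query=query, table=pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def partners(self) -> list[str]:
        return list(self.table["partner"])


@dataclass(frozen=True)
class PathwayCatalog:
    """Pathway id -> member protein set."""

    members: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        for pid, mem in self.members.items():
            if not mem:
                raise ValueError(f"pathway {pid} has no members")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayCatalog":
        """Read a 2-column TSV (pathway, comma-separated member list)."""
        df = pd.read_csv(path, sep="\t")
        return cls(
            members={
                row["pathway"]: frozenset(str(row["members"]).split(","))
                for _, row in df.iterrows()
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {"pathway": pid, "members": ",".join(sorted(mem))}
            for pid, mem in sorted(self.members.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_partners(tbl: PPITable, cutoff: float = 0.5, top_n: int = 11) -> PPITable:
    """Score filter and truncation of a PPI partner table.

    Rows with score >= ``cutoff`` are kept, sorted by descending score,
    and truncated so the retained set *including the query* has ``top_n``
    members.  The query is appended with score 1.0 when absent.  Score
    ties at the cut are all kept (the result may then exceed ``top_n``).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    df = tbl.table.copy()
    if tbl.query not in set(df["partner"]):
        df = pd.concat(
            [df, pd.DataFrame([{"partner": tbl.query, "score": 1.0}])],
            ignore_index=True,
        )
    df = df[df["score"] >= cutoff]
    query_rows = df[df["partner"] == tbl.query]
    others = df[df["partner"] != tbl.query].sort_values(
        ["score", "partner"], ascending=[False, True], kind="mergesort"
    )
    budget = top_n - len(query_rows)
    if len(others) > budget:
        cut_score = others.iloc[budget - 1]["score"] if budget > 0 else np.inf
        kept = others[others["score"] >= cut_score]
        if len(kept) > budget:
            logger.info(
                "score tie at the cut: keeping %d partners instead of %d",
                len(kept),
                budget,
            )
        others = kept
    out = pd.concat([query_rows, others]).sort_values(
        ["score", "partner"], ascending=[False, True], kind="mergesort"
    )
    return PPITable(query=tbl.query, table=out.reset_index(drop=True))


def filter_pathways(
    cat: PathwayCatalog, required: str, min_members: int = 2
) -> PathwayCatalog:
    """Keep pathways containing ``required`` with >= ``min_members`` members."""
    kept = {
        pid: mem
        for pid, mem in cat.members.items()
        if required in mem and len(mem) >= min_members
    }
    return PathwayCatalog(members=kept)


# --------------------------------------------------------------------------
# ontology handling


def load_go_graph(path: str | Path) -> nx.DiGraph:
    """Read an ontology edge list TSV: child, parent, relation[, c_e].

    Edges point child -> parent; the contribution factor defaults by
    relation type (is_a 0.8, part_of 0.6).
    """
    df = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for _, row in df.iterrows():
        rel = str(row.get("relation", "is_a"))
        ce = row.get("c_e", np.nan)
        if pd.isna(ce):
            ce = CONTRIBUTION_FACTORS.get(rel)
            if ce is None:
                raise ValueError(f"no contribution factor for relation {rel!r}")
        ce = float(ce)
        if not 0.0 < ce < 1.0:
            raise ValueError(f"contribution factor {ce} outside (0, 1)")
        g.add_edge(str(row["child"]), str(row["parent"]), relation=rel, c_e=ce)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("ontology graph contains a cycle")
    return g


def load_go_obo(path: str | Path) -> nx.DiGraph:
    """Read an OBO ontology subset (is_a / part_of) into the edge model."""
    import obonet

    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    for child, parent, rel in multi.edges(keys=True):
        if rel not in CONTRIBUTION_FACTORS:
            continue
        g.add_edge(child, parent, relation=rel, c_e=CONTRIBUTION_FACTORS[rel])
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("ontology graph contains a cycle")
    return g


@dataclass(frozen=True)
class SValueMap:
    """Wang S-values of one anchor term over its ancestor DAG."""

    term: str
    s: Mapping[str, float]

    def __post_init__(self) -> None:
        if abs(self.s[self.term] - 1.0) > 1e-12:
            raise ValueError("S_T(T) must equal 1")
        for p, v in self.s.items():
            if not 0.0 < v <= 1.0:
                raise ValueError(f"S-value of {p} out of (0, 1]: {v}")

    @property
    def ancestors(self) -> frozenset:
        return frozenset(self.s)

    @property
    def sv(self) -> float:
        return float(sum(self.s.values()))


def s_values(go: nx.DiGraph, term: str) -> SValueMap:
    """Downward-propagated S-values of ``term`` over its ancestor DAG.

    Ancestors are reached along child -> parent edges; each S_T(p) is the
    maximum over p's children inside the DAG of c_e * S_T(child),
    evaluated in topological order.
    """
    if term not in go:
        raise KeyError(f"term {term!r} not in the ontology graph")
    anc = {term} | nx.descendants(go, term)  # edges run child -> parent
    sub = go.subgraph(anc)
    s: dict[str, float] = {term: 1.0}
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        best = 0.0
        for child, _, data in sub.in_edges(node, data=True):
            if child in s:
                best = max(best, data["c_e"] * s[child])
        s[node] = best
    return SValueMap(term=term, s=s)


def semantic_value(sv: SValueMap) -> float:
    """SV(T): the sum of S-values over the ancestor set (including T)."""
    return sv.sv


def term_similarity(go: nx.DiGraph, t: str, q: str) -> float:
    """Wang similarity SS_w(T, Q); 0 when the ancestor DAGs are disjoint."""
    st, sq = s_values(go, t), s_values(go, q)
    shared = st.ancestors & sq.ancestors
    if not shared:
        return 0.0
    num = sum(st.s[p] + sq.s[p] for p in shared)
    return float(num / (st.sv + sq.sv))


def bma_similarity(
    set1: Iterable[str], set2: Iterable[str], go: nx.DiGraph
) -> float:
    """Best-match average between two GO term sets.

    Each term's best SS_w match in the other set is averaged over both
    directions: (sum of row maxima + sum of column maxima) / (i + j).
    """
    terms1, terms2 = sorted(set(set1)), sorted(set(set2))
    if not terms1 or not terms2:
        raise ValueError("BMA needs two non-empty term sets")
    maps = {t: s_values(go, t) for t in set(terms1) | set(terms2)}
    sim = np.zeros((len(terms1), len(terms2)))
    for i, t in enumerate(terms1):
        st = maps[t]
        for j, q in enumerate(terms2):
            sq = maps[q]
            shared = st.ancestors & sq.ancestors
            if shared:
                num = sum(st.s[p] + sq.s[p] for p in shared)
                sim[i, j] = num / (st.sv + sq.sv)
    return float((sim.max(axis=1).sum() + sim.max(axis=0).sum()) / (len(terms1) + len(terms2)))


def build_semantic_graph(
    cat: PathwayCatalog,
    annotations: pd.DataFrame,
    go: nx.DiGraph,
    ontology: str = "BP",
    strong_quantile: float = 0.75,
) -> nx.Graph:
    """Pathway semantic graph: nodes = pathways, edges = BMA similarities.

    A pathway's term set is the union of its member proteins' annotations
    in the chosen ontology (``annotations`` columns: protein, term,
    ontology); members without annotations are dropped with a warning.
    Zero-weight edges are omitted; edges at or above the
    ``strong_quantile`` of retained weights are flagged ``strong`` (the
    "bold" edges of a rendered pathway graph).
    """
    if len(cat.members) < 2:
        raise ValueError("semantic graph needs at least 2 pathways")
    ann = annotations[annotations["ontology"] == ontology]
    by_protein: dict[str, set] = {}
    for _, row in ann.iterrows():
        by_protein.setdefault(str(row["protein"]), set()).add(str(row["term"]))
    term_sets: dict[str, set] = {}
    for pid, mem in sorted(cat.members.items()):
        terms: set = set()
        for prot in sorted(mem):
            if prot in by_protein:
                terms |= by_protein[prot]
            else:
                logger.warning(
                    "pathway %s member %s has no %s annotations", pid, prot, ontology
                )
        term_sets[pid] = terms
    g = nx.Graph(ontology=ontology, provenance="semantic")
    g.add_nodes_from(term_sets)
    pids = sorted(term_sets)
    weights = []
    for i, p1 in enumerate(pids):
        for p2 in pids[i + 1 :]:
            if not term_sets[p1] or not term_sets[p2]:
                continue
            w = bma_similarity(term_sets[p1], term_sets[p2], go)
            if w > 0.0:
                g.add_edge(p1, p2, weight=w, strong=False)
                weights.append(w)
    if weights:
        threshold = float(np.quantile(weights, strong_quantile))
        for u, v, data in g.edges(data=True):
            data["strong"] = bool(data["weight"] >= threshold)
    return g


def pagerank(
    g: nx.Graph,
    damping: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> pd.Series:
    """Weighted PageRank of a pathway semantic graph.

    Power iteration of PR(n) = d * sum_m PR(m) w_mn / W_m + (1-d)/N with
    uniform initialization; W_m is m's total incident weight.  The default
    d = 1 is the literal rank equation; because the plain iteration can
    oscillate on bipartite graphs, a Cesàro-averaged ("lazy") iteration
    with the same fixed point is tried next, and if that also fails the
    solver falls back to d = 0.85 with a warning.  Isolated nodes receive
    teleport mass only.  Returns scores summing to 1, sorted descending
    (id ascending on ties).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not 0.0 < damping <= 1.0:
        raise ValueError(f"damping must lie in (0, 1], got {damping}")
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    deg = A.sum(axis=1)
    if g.number_of_edges() == 0:
        # no walk to iterate: teleport-only stationary state is uniform
        x = np.full(n, 1.0 / n)
        return pd.Series(x, index=nodes, name="pagerank")
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(deg[None, :] > 0, A / deg[None, :], 0.0)  # column-stochastic

    def iterate(d: float, lazy: bool) -> np.ndarray | None:
        x = np.full(n, 1.0 / n)
        teleport = (1.0 - d) / n
        for _ in range(max_iter):
            x_new = d * (T @ x) + teleport
            if lazy:
                x_new = 0.5 * (x + x_new)
            if np.abs(x_new - x).sum() < tol:
                return x_new
            x = x_new
        return None

    x = iterate(damping, lazy=False)
    if x is None:
        x = iterate(damping, lazy=True)
    if x is None:
        logger.warning(
            "PageRank did not converge at damping %.3f; falling back to 0.85",
            damping,
        )
        x = iterate(0.85, lazy=True)
        if x is None:
            raise RuntimeError("PageRank failed to converge even at damping 0.85")
    x = np.maximum(x, 0.0)
    x /= x.sum()
    s = pd.Series(x, index=nodes, name="pagerank")
    return s.sort_values(ascending=False, kind="mergesort").reindex(
        sorted(s.index, key=lambda v: (-s[v], str(v)))
    )
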