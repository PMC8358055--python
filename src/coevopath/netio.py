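"""Text exchange formats for residue and pathway networks."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .graphs import CommunityPartition

__all__ = [
    "write_network",
    "read_edge_list",
    "write_partition",
    "write_series",
]


def write_network(g: nx.Graph, prefix: str | Path) -> tuple[Path, Path]:
    """Export a weighted graph as edge-list TSV and GraphML.

    Returns the two paths written (``<prefix>.tsv``, ``<prefix>.graphml``).
    Extra boolean edge attributes (e.g. the ``strong`` flag of semantic
    graphs) become additional TSV columns.
    """
    prefix = Path(prefix)
    rows = []
    extra_cols: set[str] = set()
    for u, v, data in g.edges(data=True):
        row = {"source": u, "target": v, "weight": data.get("weight", 1.0)}
        for key, val in data.items():
            if key != "weight":
                row[key] = val
                extra_cols.add(key)
        rows.append(row)
    cols = ["source", "target", "weight", *sorted(extra_cols)]
    df = pd.DataFrame(rows, columns=cols)
    tsv = prefix.with_suffix(".tsv")
    df.to_csv(tsv, sep="\t", index=False)
    graphml = prefix.with_suffix(".graphml")
    nx.write_graphml(g, graphml)
    return tsv, graphml


def read_edge_list(path: str | Path, provenance: str = "") -> nx.Graph:
    """Read a weighted edge-list TSV back into a graph."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph(provenance=provenance)

    def _node(value):
        # integer residue labels survive the text round-trip as ints
        if isinstance(value, float) and value.is_integer():
            return int(value)
        if hasattr(value, "item"):
            value = value.item()
            if isinstance(value, float) and value.is_integer():
                return int(value)
        return value

    for _, row in df.iterrows():
        attrs = {k: row[k] for k in df.columns if k not in ("source", "target")}
        g.add_edge(_node(row["source"]), _node(row["target"]), **attrs)
    return g


def write_partition(p: CommunityPartition, path: str | Path) -> None:
    """Write a community partition as TSV (node, community_id)."""
    rows = []
    for cid, comm in enumerate(p.communities):
        for node in sorted(comm, key=str):
            rows.append({"node": node, "community_id": cid})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_series(values: dict | pd.Series, path: str | Path, value_name: str) -> None:
    """Write a node -> value mapping as a 2-column TSV."""
    s = pd.Series(values, name=value_name)
    s.index.name = "node"
    s.to_csv(path, sep="\t")
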