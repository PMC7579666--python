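"""Directed-graph centrality analysis of the interaction network.

All measures are computed on the *unweighted support graph* of the reduced
adjacency — an edge exists wherever the trigger probability is positive —
since the binary encoding makes every edge weight identical.

Interpretation in cascade terms: main triggering events (sources) show high
out-degree and closeness; main triggered events (sinks) show high in-degree;
the catalysts that promote cascading show high betweenness.

Conventions (stated so results are reproducible bit-for-bit):

* degrees count distinct non-zero cells; a self-loop adds one to both the
  in- and out-degree of its node;
* closeness is the *harmonic* out-closeness ``c(i) = (1/(n−1)) Σ_{j≠i}
  1/d(i,j)`` with ``1/∞ = 0``, which stays well-defined on graphs that are
  not strongly connected (unreachable nodes simply contribute nothing);
* betweenness is the directed shortest-path measure ``b(v) = Σ_{s≠v≠t}
  σ_st(v)/σ_st`` with fractional counting over tied shortest paths, endpoints
  excluded, self-loops ignored, unnormalized by graph size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .markov import ReducedAdjacency
from .taxonomy import PerilRegistry

__all__ = [
    "CentralityReport",
    "support_graph",
    "degree_centralities",
    "closeness_centrality",
    "betweenness_centrality",
    "centrality_report",
    "export_graph",
]

EXPORT_FORMATS = ("edgelist", "dot", "graphml")


def support_graph(a: ReducedAdjacency, include_self_loops: bool = True) -> nx.DiGraph:
    """Unweighted directed support graph of A (edge iff p_ij > 0)."""
    g = nx.DiGraph()
    g.add_nodes_from(a.labels)
    rows, cols = np.nonzero(a.values > 0)
    for i, j in zip(rows, cols):
        if i == j and not include_self_loops:
            continue
        g.add_edge(a.labels[i], a.labels[j], probability=float(a.values[i, j]))
    return g


def degree_centralities(a: ReducedAdjacency, include_self_loops: bool = True
                        ) -> tuple[pd.Series, pd.Series]:
    """(in_degree, out_degree) — counts of non-zero column/row cells."""
    mask = a.values > 0
    if not include_self_loops:
        mask = mask & ~np.eye(a.n, dtype=bool)
    labels = list(a.labels)
    in_deg = pd.Series(mask.sum(axis=0), index=labels, name="in_degree")
    out_deg = pd.Series(mask.sum(axis=1), index=labels, name="out_degree")
    return in_deg, out_deg


def closeness_centrality(a: ReducedAdjacency) -> pd.Series:
    """Harmonic out-closeness on the unweighted support graph."""
    g = support_graph(a)
    n = a.n
    scores = {}
    for node in a.labels:
        dist = nx.single_source_shortest_path_length(g, node)
        total = sum(1.0 / d for other, d in dist.items() if other != node and d > 0)
        scores[node] = total / (n - 1) if n > 1 else 0.0
    return pd.Series(scores, name="closeness").reindex(list(a.labels))


def betweenness_centrality(a: ReducedAdjacency) -> pd.Series:
    """Directed betweenness with fractional pair counting, unnormalized."""
    g = support_graph(a, include_self_loops=False)
    scores = nx.betweenness_centrality(g, normalized=False)
    return pd.Series(scores, name="betweenness").reindex(list(a.labels))


@dataclass(frozen=True)
class CentralityReport:
    """Per-node centrality table plus top-k rankings per measure."""

    table: pd.DataFrame
    top_k: dict[str, list[str]]

    def to_json(self) -> str:
        payload = {
            "nodes": {
                node: {k: (int(v) if k.endswith("degree") else float(v))
                       for k, v in row.items()}
                for node, row in self.table.iterrows()
            },
            "top_k": self.top_k,
        }
        return json.dumps(payload, indent=2)


def centrality_report(a: ReducedAdjacency, k: int = 3,
                      include_self_loops: bool = True) -> CentralityReport:
    """All four centralities plus the top-k peril ids per measure.

    Rankings break ties lexicographically on the peril id so the report is
    deterministic.
    """
    in_deg, out_deg = degree_centralities(a, include_self_loops=include_self_loops)
    table = pd.DataFrame({
        "in_degree": in_deg,
        "out_degree": out_deg,
        "closeness": closeness_centrality(a),
        "betweenness": betweenness_centrality(a),
    })
    top_k = {}
    for measure in table.columns:
        ranked = sorted(table.index, key=lambda node: (-table.at[node, measure], node))
        top_k[measure] = ranked[:k]
    return CentralityReport(table=table, top_k=top_k)


def export_graph(a: ReducedAdjacency, fmt: str, path: str | Path,
                 registry: PerilRegistry | None = None) -> None:
    """Serialize the support graph with node attributes.

    Nodes carry the peril id, system label (when a registry is given) and all
    four centrality values; edges carry the trigger probability.  Formats:
    ``edgelist`` (TSV), ``dot``, ``graphml``.
    """
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {EXPORT_FORMATS}")
    path = Path(path)
    g = support_graph(a)
    report = centrality_report(a)
    for node in g.nodes:
        row = report.table.loc[node]
        g.nodes[node]["in_degree"] = int(row["in_degree"])
        g.nodes[node]["out_degree"] = int(row["out_degree"])
        g.nodes[node]["closeness"] = float(row["closeness"])
        g.nodes[node]["betweenness"] = float(row["betweenness"])
        if registry is not None and node in registry:
            g.nodes[node]["system"] = registry.system(node)
            g.nodes[node]["peril_name"] = registry[node].name

    if fmt == "edgelist":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tprobability\n")
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data['probability']:g}\n")
    elif fmt == "dot":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("digraph cascades {\n")
            for node, data in sorted(g.nodes(data=True)):
                attrs = ", ".join(f'{k}="{v}"' for k, v in sorted(data.items()))
                fh.write(f'  "{node}" [{attrs}];\n')
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f'  "{u}" -> "{v}" [probability="{data["probability"]:g}"];\n')
            fh.write("}\n")
    else:
        nx.write_graphml(g, path)
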