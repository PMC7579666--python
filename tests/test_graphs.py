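"""Centrality measures on the unweighted support graph.

Betweenness is cross-checked against a brute-force enumeration of all
shortest paths on small random graphs — an oracle independent of the
shortest-path-counting algorithm used by the implementation.
"""

from itertools import permutations

import networkx as nx
import numpy as np
import pytest

from cascadyn import (
    ReducedAdjacency,
    betweenness_centrality,
    centrality_report,
    closeness_centrality,
    degree_centralities,
    export_graph,
    support_graph,
)


def adjacency_from_edges(n, edges, p=0.1):
    values = np.zeros((n, n))
    for i, j in edges:
        values[i, j] = p
    return ReducedAdjacency(tuple(f"V{i}" for i in range(n)), values)


CHAIN = adjacency_from_edges(3, [(0, 1), (1, 2)])


def test_chain_degrees():
    in_deg, out_deg = degree_centralities(CHAIN)
    assert list(in_deg) == [0, 1, 1]
    assert list(out_deg) == [1, 1, 0]


def test_self_loop_counts_once_in_each_degree():
    a = adjacency_from_edges(2, [(0, 0), (0, 1)])
    in_deg, out_deg = degree_centralities(a)
    assert in_deg["V0"] == 1 and out_deg["V0"] == 2
    in_deg, out_deg = degree_centralities(a, include_self_loops=False)
    assert in_deg["V0"] == 0 and out_deg["V0"] == 1


def test_degree_sums_equal_edge_count(empirical):
    in_deg, out_deg = degree_centralities(empirical)
    nnz = int((empirical.values > 0).sum())
    assert in_deg.sum() == out_deg.sum() == nnz


def test_zero_matrix_all_centralities_zero():
    a = adjacency_from_edges(4, [])
    in_deg, out_deg = degree_centralities(a)
    assert not in_deg.any() and not out_deg.any()
    assert not closeness_centrality(a).any()
    assert not betweenness_centrality(a).any()


def test_chain_closeness_by_hand():
    """Node 0 reaches 1 at distance 1 and 2 at distance 2: (1 + 1/2)/2."""
    c = closeness_centrality(CHAIN)
    assert c["V0"] == pytest.approx(0.75)
    assert c["V1"] == pytest.approx(0.5)
    assert c["V2"] == 0.0


def test_star_center_closeness_is_one():
    a = adjacency_from_edges(5, [(0, j) for j in range(1, 5)])
    assert closeness_centrality(a)["V0"] == pytest.approx(1.0)


def test_chain_betweenness():
    b = betweenness_centrality(CHAIN)
    assert list(b) == [0.0, 1.0, 0.0]


def test_complete_digraph_betweenness_zero():
    a = adjacency_from_edges(4, [(i, j) for i in range(4) for j in range(4) if i != j])
    assert not betweenness_centrality(a).any()


def brute_force_betweenness(a: ReducedAdjacency) -> dict[str, float]:
    """Enumerate every shortest path explicitly (fractional pair counting)."""
    g = support_graph(a, include_self_loops=False)
    scores = {v: 0.0 for v in a.labels}
    for s, t in permutations(a.labels, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                scores[v] += 1.0 / len(paths)
    return scores


@pytest.mark.parametrize("seed", range(5))
def test_betweenness_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 7))
    edges = [(i, j) for i in range(n) for j in range(n) if rng.random() < 0.4]
    a = adjacency_from_edges(n, edges)
    expected = brute_force_betweenness(a)
    computed = betweenness_centrality(a)
    for v in a.labels:
        assert computed[v] == pytest.approx(expected[v], abs=1e-12)


def test_zero_betweenness_node_removal_preserves_paths():
    """Removing a zero-betweenness node keeps every avoided s–t pair connected."""
    rng = np.random.default_rng(3)
    n = 6
    edges = [(i, j) for i in range(n) for j in range(n) if i != j and rng.random() < 0.35]
    a = adjacency_from_edges(n, edges)
    g = support_graph(a, include_self_loops=False)
    b = betweenness_centrality(a)
    for node in a.labels:
        if b[node] != 0:
            continue
        reduced = g.copy()
        reduced.remove_node(node)
        for s, t in permutations(a.labels, 2):
            if node in (s, t):
                continue
            if nx.has_path(g, s, t) and node not in min(
                    nx.all_shortest_paths(g, s, t), key=len):
                assert nx.has_path(reduced, s, t)


def test_report_rankings_are_deterministic(empirical):
    rep1 = centrality_report(empirical)
    rep2 = centrality_report(empirical)
    assert rep1.top_k == rep2.top_k
    assert set(rep1.table.columns) == {"in_degree", "out_degree", "closeness", "betweenness"}


# -- exports ----------------------------------------------------------------

def test_edgelist_export(tmp_path):
    path = tmp_path / "g.tsv"
    export_graph(CHAIN, "edgelist", path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "source\ttarget\tprobability"
    assert len(lines) == 3


def test_graphml_export_carries_attributes(tmp_path, empirical, registry):
    path = tmp_path / "g.graphml"
    export_graph(empirical, "graphml", path, registry)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == 19
    assert g.nodes["NF"]["system"] == "anthropogenic"
    assert g.nodes["NF"]["in_degree"] == 11


def test_empty_matrix_export(tmp_path, registry):
    a = ReducedAdjacency(registry.ids, np.zeros((19, 19)))
    path = tmp_path / "g.dot"
    export_graph(a, "dot", path, registry)
    text = path.read_text()
    assert "->" not in text            # no edges
    assert text.count("];") == 19      # every peril present as an isolated node


def test_unknown_export_format(tmp_path):
    with pytest.raises(ValueError, match="format"):
        export_graph(CHAIN, "svg", tmp_path / "g.svg")
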