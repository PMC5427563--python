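"""PPI network assembly, topology metrics and random-null comparison.

Predicted interactions are assembled into an undirected simple graph.
Topology is summarized by the mean degree 2|E|/|V|, the diameter of the
largest connected component, and the mean local (Watts-Strogatz) clustering
coefficient with degree<2 nodes contributing 0; global transitivity is also
reported for transparency. The null model is a uniform G(n, m) random graph
with the same number of nodes and edges. Hive-plot grouping assigns nodes to
axes by degree (low < 50, medium 50-80, high > 80) ordered within each axis
by ascending local clustering coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "PPINetwork",
    "NetworkMetrics",
    "EdgeLabel",
    "build_network",
    "network_metrics",
    "random_network",
    "overlay_reference",
    "hive_groups",
    "write_edgelist",
    "read_edgelist",
]

#: hive-plot degree-axis boundaries: low d<50, medium 50<=d<=80, high d>80
HIVE_LOW_MAX = 49
HIVE_MEDIUM_MAX = 80


@dataclass
class PPINetwork:
    """Undirected simple interaction graph plus assembly bookkeeping."""

    graph: nx.Graph
    n_self_skipped: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


@dataclass(frozen=True)
class NetworkMetrics:
    mean_degree: float
    diameter: int
    mean_clustering_coefficient: float
    transitivity: float
    n_nodes: int
    n_edges: int


@dataclass(frozen=True)
class EdgeLabel:
    edge: frozenset
    label: str  # positive_prediction | true_positive | false_negative


def build_network(predicted_pairs: Iterable[tuple[str, str]]) -> PPINetwork:
    """Deduplicated undirected simple graph; self-pairs skipped and counted."""
    g = nx.Graph()
    skipped = 0
    for a, b in predicted_pairs:
        if a == b:
            skipped += 1
            continue
        g.add_edge(a, b)
    return PPINetwork(graph=g, n_self_skipped=skipped)


def network_metrics(net: PPINetwork) -> NetworkMetrics:
    """Mean degree, largest-component diameter, and clustering coefficients."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n, m = g.number_of_nodes(), g.number_of_edges()
    if m:
        largest = max(nx.connected_components(g), key=len)
        diameter = nx.diameter(g.subgraph(largest))
    else:
        diameter = 0
    return NetworkMetrics(
        mean_degree=2.0 * m / n,
        diameter=int(diameter),
        mean_clustering_coefficient=float(nx.average_clustering(g)),
        transitivity=float(nx.transitivity(g)),
        n_nodes=n,
        n_edges=m,
    )


def random_network(n_nodes: int, n_edges: int, seed: int) -> PPINetwork:
    """Uniform G(n, m) simple random graph with exactly the requested counts."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not (0 <= n_edges <= max_edges):
        raise ValueError(f"cannot place {n_edges} edges among {n_nodes} nodes")
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    return PPINetwork(graph=g)


def overlay_reference(
    net: PPINetwork, reference_edges: Iterable[tuple[str, str]]
) -> tuple[list[EdgeLabel], dict[str, int]]:
    """Label predicted vs reference edges for network overlay plots.

    predicted ∩ reference -> true_positive; predicted \\ reference ->
    positive_prediction; reference \\ predicted -> false_negative. The three
    label sets partition predicted ∪ reference.
    """
    predicted = net.edges
    reference = {frozenset(e) for e in reference_edges if e[0] != e[1]}
    labels = (
        [EdgeLabel(e, "true_positive") for e in sorted(predicted & reference, key=sorted)]
        + [
            EdgeLabel(e, "positive_prediction")
            for e in sorted(predicted - reference, key=sorted)
        ]
        + [
            EdgeLabel(e, "false_negative")
            for e in sorted(reference - predicted, key=sorted)
        ]
    )
    summary = {
        "true_positive": len(predicted & reference),
        "positive_prediction": len(predicted - reference),
        "false_negative": len(reference - predicted),
    }
    return labels, summary


def hive_groups(net: PPINetwork) -> dict[str, tuple[str, int]]:
    """Hive-plot axis assignment and within-axis order per node.

    Axis by degree: 'low' (d < 50), 'medium' (50 <= d <= 80), 'high'
    (d > 80); order within an axis ascends by local clustering coefficient,
    ties broken by node id.
    """
    g = net.graph
    clustering = nx.clustering(g)
    out: dict[str, tuple[str, int]] = {}
    by_axis: dict[str, list] = {"low": [], "medium": [], "high": []}
    for node in g.nodes:
        d = g.degree[node]
        axis = "low" if d <= HIVE_LOW_MAX else "medium" if d <= HIVE_MEDIUM_MAX else "high"
        by_axis[axis].append(node)
    for axis, members in by_axis.items():
        members.sort(key=lambda v: (clustering[v], str(v)))
        for order, node in enumerate(members):
            out[node] = (axis, order)
    return out


def write_edgelist(
    edges: Iterable[Sequence], path, header: tuple[str, ...] = ("protein_a", "protein_b")
) -> None:
    lines = ["\t".join(header)]
    for edge in edges:
        lines.append("\t".join(str(x) for x in edge))
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path) -> list[tuple[str, ...]]:
    lines = Path(path).read_text().splitlines()
    return [tuple(line.split("\t")) for line in lines[1:] if line.strip()]
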