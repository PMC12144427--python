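"""Directed and undirected weighted play networks.

Nodes are animals sized by the total play they initiated; directed edges are
weighted by the proportion of the initiator's play directed at the recipient
(so comparisons of preference strength survive large differences in play
output); the undirected variant weights each dyad by its total play in both
directions.  ``preference_network`` keeps only the strong preferences
(index >= 2, solid edges) and avoidances (index <= 0.25, dashed edges).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .events import CountMatrix, to_proportions


def build_directed_network(counts: CountMatrix) -> nx.DiGraph:
    """Directed play network: node attr ``total_initiated``; edge attrs
    ``weight`` (proportion of the initiator's play) and ``count``."""
    props = to_proportions(counts)
    g = nx.DiGraph(group_id=counts.group_id, day=counts.day)
    totals = counts.row_totals
    for i, a in enumerate(counts.labels):
        g.add_node(a, total_initiated=int(totals[i]))
    for i, a in enumerate(counts.labels):
        for j, b in enumerate(counts.labels):
            if i != j and counts.counts[i, j] > 0:
                g.add_edge(a, b, weight=float(props.proportions[i, j]),
                           count=int(counts.counts[i, j]))
    return g


def build_undirected_network(counts: CountMatrix) -> nx.Graph:
    """Undirected play network: edge weight = total play between the pair."""
    g = nx.Graph(group_id=counts.group_id, day=counts.day)
    totals = counts.row_totals
    for i, a in enumerate(counts.labels):
        g.add_node(a, total_initiated=int(totals[i]))
    for i in range(counts.k):
        for j in range(i + 1, counts.k):
            w = int(counts.counts[i, j] + counts.counts[j, i])
            if w > 0:
                g.add_edge(counts.labels[i], counts.labels[j], weight=w)
    return g


def preference_network(index_table: pd.DataFrame,
                       labels: tuple[str, ...] | None = None) -> nx.DiGraph:
    """Network of classified preferences for one group-day.

    Keeps only strong_preferred dyads (edge style ``solid``) and avoided
    dyads (style ``dashed``); all animals remain as nodes.
    """
    g = nx.DiGraph()
    if labels is None:
        labels = tuple(sorted(set(index_table["initiator"])
                              | set(index_table["recipient"])))
    g.add_nodes_from(labels)
    keep = index_table[index_table["classification"].isin(
        ["strong_preferred", "avoided"])]
    for row in keep.to_dict("records"):
        style = ("solid" if row["classification"] == "strong_preferred"
                 else "dashed")
        g.add_edge(row["initiator"], row["recipient"],
                   index=float(row["index"]), style=style,
                   classification=row["classification"])
    return g


def eigenvector_centrality(graph: nx.Graph, max_iter: int = 1000,
                           tol: float = 1e-10
                           ) -> tuple[dict[str, float], bool]:
    """Weighted eigenvector centrality, normalised to max 1 per component.

    Directed graphs are analysed on their undirected weighted projection.
    Disconnected graphs are scored per connected component and flagged
    (second return value ``True`` when disconnected).  Isolated nodes score
    0.  Non-convergence raises with the iteration count.
    """
    if graph.is_directed():
        und = nx.Graph()
        und.add_nodes_from(graph.nodes(data=True))
        for a, b, data in graph.edges(data=True):
            w = data.get("weight", 1.0)
            if und.has_edge(a, b):
                und[a][b]["weight"] += w
            else:
                und.add_edge(a, b, weight=w)
        graph = und
    components = list(nx.connected_components(graph))
    disconnected = len(components) > 1
    scores: dict[str, float] = {}
    for comp in components:
        if len(comp) == 1:
            scores[next(iter(comp))] = 0.0
            continue
        sub = graph.subgraph(comp)
        try:
            cent = nx.eigenvector_centrality(sub, weight="weight",
                                             max_iter=max_iter, tol=tol)
        except nx.PowerIterationFailedConvergence as exc:
            raise RuntimeError(
                f"eigenvector centrality did not converge in {max_iter} "
                "iterations") from exc
        top = max(cent.values())
        for node, v in cent.items():
            scores[node] = v / top if top > 0 else 0.0
    return scores, disconnected


# ---------------------------------------------------------------------------
# exports


def network_edgelist(graph: nx.Graph | nx.DiGraph) -> pd.DataFrame:
    rows = []
    for a, b, data in graph.edges(data=True):
        row = {"source": a, "target": b}
        row.update({k: v for k, v in data.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_graphml(graph: nx.Graph | nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def plot_network(graph: nx.Graph | nx.DiGraph, path: str | Path,
                 title: str = "") -> None:
    """Static plot: circular layout (deterministic), node size proportional
    to play initiated, edge width to weight, dashed edges for avoidances."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.circular_layout(sorted(graph.nodes))
    fig, ax = plt.subplots(figsize=(4, 4))
    sizes = [300 + 8 * graph.nodes[n].get("total_initiated", 10)
             for n in graph.nodes]
    nx.draw_networkx_nodes(graph, pos, node_size=sizes, node_color="#9ecae1",
                           ax=ax)
    nx.draw_networkx_labels(graph, pos, ax=ax)
    solid = [(a, b) for a, b, d in graph.edges(data=True)
             if d.get("style", "solid") == "solid"]
    dashed = [(a, b) for a, b, d in graph.edges(data=True)
              if d.get("style") == "dashed"]
    widths = lambda edges: [0.5 + 4 * graph[a][b].get("weight", 0.2)
                            for a, b in edges]
    nx.draw_networkx_edges(graph, pos, edgelist=solid, width=widths(solid),
                           ax=ax)
    if dashed:
        nx.draw_networkx_edges(graph, pos, edgelist=dashed, style="dashed",
                               width=widths(dashed), edge_color="#888", ax=ax)
    ax.set_title(title)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
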