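"""Graph container, edge-list I/O and summary statistics.

Networks are undirected simple graphs by default (optionally directed or
weighted), stored as :class:`networkx` graphs behind a thin :class:`Network`
wrapper that enforces simplicity and carries the weighted flag.  Node labels
are opaque strings: real edge lists use integer IDs, names, URLs — nothing
here assumes contiguity or numeric order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NetworkSummary",
    "read_edge_list",
    "write_edge_list",
    "degrees",
    "shortest_path_lengths",
    "summary_stats",
]


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list lines; message names the line number."""


@dataclass
class Network:
    """A simple network G(V, E): no self-loops, no duplicate edges.

    Parameters
    ----------
    graph
        ``nx.Graph`` (undirected) or ``nx.DiGraph``.  Edges may carry a
        positive ``weight`` attribute when ``weighted`` is set.
    weighted
        Whether edge weights are meaningful.  Unweighted edges are treated
        as weight 1 wherever a weighted quantity is requested.
    """

    graph: "nx.Graph | nx.DiGraph"
    weighted: bool = False

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops[:3]}")
        if self.weighted:
            for u, v, d in self.graph.edges(data=True):
                w = d.get("weight")
                if w is None or not (w > 0):
                    raise ValueError(f"edge ({u}, {v}) needs a positive weight, got {w!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def neighbors(self, node) -> list:
        return list(self.graph.neighbors(node))

    def strength(self, node) -> float:
        """Sum of incident edge weights (equals degree when unweighted)."""
        if not self.weighted:
            return float(self.graph.degree(node))
        return float(self.graph.degree(node, weight="weight"))

    def copy(self) -> "Network":
        return Network(self.graph.copy(), weighted=self.weighted)


@dataclass
class NetworkSummary:
    """Per-network topological summary (the usual N, L, <k>, <k^2>, <d>, C, r)."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    mean_squared_degree: float
    mean_distance: float
    clustering: float
    assortativity: float

    def as_row(self) -> dict:
        return {
            "N": self.n_nodes,
            "L": self.n_edges,
            "k_mean": self.mean_degree,
            "k2_mean": self.mean_squared_degree,
            "d_mean": self.mean_distance,
            "C": self.clustering,
            "r": self.assortativity,
        }


def read_edge_list(
    path: str | Path,
    directed: bool = False,
    weighted: bool = False,
) -> Network:
    """Read a whitespace-separated edge list into a :class:`Network`.

    Lines starting with ``#`` are comments.  Each data line holds two node
    labels and, when ``weighted``, a third positive numeric column.
    Self-loops and duplicate edges (including reciprocal pairs read as
    undirected) are dropped with a logged warning; node labels are kept
    verbatim.
    """
    path = Path(path)
    g: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    n_loops = n_dups = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgeListParseError(f"{path}:{lineno}: expected >=2 tokens, got {line!r}")
            u, v = tokens[0], tokens[1]
            if weighted:
                if len(tokens) < 3:
                    raise EdgeListParseError(f"{path}:{lineno}: weighted list needs a third column")
                try:
                    w = float(tokens[2])
                except ValueError as exc:
                    raise EdgeListParseError(f"{path}:{lineno}: bad weight {tokens[2]!r}") from exc
                if not w > 0:
                    raise ValueError(f"{path}:{lineno}: nonpositive weight {w}")
            if u == v:
                n_loops += 1
                continue
            if g.has_edge(u, v):
                n_dups += 1
                continue
            g.add_edge(u, v, **({"weight": w} if weighted else {}))
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    if n_dups:
        logger.warning("%s: dropped %d duplicate edge(s)", path, n_dups)
    return Network(g, weighted=weighted)


def write_edge_list(network: Network, path: str | Path, header: Iterable[str] = ()) -> None:
    """Write a network back to the edge-list format ``read_edge_list`` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for u, v, d in network.graph.edges(data=True):
            if network.weighted:
                fh.write(f"{u}\t{v}\t{d['weight']:g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def degrees(network: Network) -> dict:
    """Node -> degree.  Directed networks get ``{'in': ..., 'out': ...}``."""
    g = network.graph
    if network.directed:
        return {
            "in": {n: d for n, d in g.in_degree()},
            "out": {n: d for n, d in g.out_degree()},
        }
    return {n: d for n, d in g.degree()}


def shortest_path_lengths(network: Network, source) -> dict:
    """BFS hop counts from ``source``; unreachable nodes are absent."""
    if source not in network.graph:
        raise KeyError(f"unknown source node {source!r}")
    return dict(nx.single_source_shortest_path_length(network.graph, source))


def summary_stats(network: Network) -> NetworkSummary:
    """Topological summary of an undirected network.

    Clustering is the mean local clustering coefficient over nodes of degree
    at least 2 (degree-1 nodes have no triples and are excluded rather than
    averaged in as zeros).  Assortativity is the degree–degree Pearson
    coefficient over edge endpoint pairs, both orientations of each edge.
    Mean distance averages hop counts over reachable ordered pairs only, so
    disconnected components contribute no infinities.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    degs = [d for _, d in g.degree()]
    n = len(degs)
    mean_k = sum(degs) / n
    mean_k2 = sum(d * d for d in degs) / n

    eligible = [v for v, d in g.degree() if d >= 2]
    if eligible:
        local = nx.clustering(g, nodes=eligible)
        clustering = sum(local.values()) / len(eligible)
    else:
        logger.warning("all nodes have degree <= 1; clustering reported as 0")
        clustering = 0.0

    total = 0
    pairs = 0
    for node in g:
        dist = nx.single_source_shortest_path_length(g, node)
        total += sum(dist.values())
        pairs += len(dist) - 1  # exclude the source itself
    mean_distance = total / pairs if pairs else 0.0

    try:
        import warnings

        with warnings.catch_warnings():
            # regular graphs have zero degree variance; report r = 0
            warnings.simplefilter("ignore", RuntimeWarning)
            r = nx.degree_assortativity_coefficient(g)
        if math.isnan(r):
            r = 0.0
    except (ZeroDivisionError, ValueError):
        r = 0.0

    return NetworkSummary(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        mean_degree=mean_k,
        mean_squared_degree=mean_k2,
        mean_distance=mean_distance,
        clustering=clustering,
        assortativity=float(r),
    )
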