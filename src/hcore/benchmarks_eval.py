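"""Benchmark centralities and the rank-correlation evaluation.

The Kendall tau used throughout divides the concordant-minus-discordant
pair count by the total number of unordered pairs N(N-1)/2, with tied pairs
(in either coordinate) contributing to neither count.  This is the tau-a
denominator with a tie-dropping numerator — deliberately NOT the common
tau-b, which rescales the denominator by the tie counts.  With heavily tied
integer indices (coreness, H-indices) the two can differ noticeably; the
variant here is the one the influence tables are scored with.

Closeness is the reciprocal of the sum of geodesic distances to reachable
nodes; betweenness is the unnormalized geodesic-share sum over unordered
source-target pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .graph_core import Network
from .h_family import HIndexTable
from .spreading import InfluenceTable

logger = logging.getLogger(__name__)

__all__ = [
    "RankCorrelation",
    "kendall_tau",
    "closeness",
    "betweenness",
    "correlation_report",
]


@dataclass
class RankCorrelation:
    """Kendall tau with its concordant/discordant pair counts.

    tau = (concordant - discordant) / (n_items * (n_items - 1) / 2);
    tied pairs are excluded from both counts but kept in the denominator.
    """

    tau: float
    concordant: int
    discordant: int
    n_items: int


def _merge_count_inversions(xs: list) -> int:
    """Count strict inversions (i < j with xs[i] > xs[j]) by merge sort."""
    n = len(xs)
    if n < 2:
        return 0
    buf = list(xs)
    tmp = [0] * n
    inv = 0
    width = 1
    while width < n:
        for lo in range(0, n, 2 * width):
            mid = min(lo + width, n)
            hi = min(lo + 2 * width, n)
            i, j, k = lo, mid, lo
            while i < mid and j < hi:
                if buf[i] <= buf[j]:
                    tmp[k] = buf[i]
                    i += 1
                else:
                    tmp[k] = buf[j]
                    j += 1
                    inv += mid - i  # every remaining left element beats buf[j]
                k += 1
            tmp[k:hi] = buf[i:mid] if i < mid else buf[j:hi]
            buf[lo:hi] = tmp[lo:hi]
        width *= 2
    return inv


def _tie_pairs(sorted_vals: list) -> int:
    """Sum over tie groups of t*(t-1)//2 in an already-sorted list."""
    total = 0
    run = 1
    for a, b in zip(sorted_vals, sorted_vals[1:]):
        if a == b:
            run += 1
        else:
            total += run * (run - 1) // 2
            run = 1
    total += run * (run - 1) // 2
    return total


def kendall_tau(x, y) -> RankCorrelation:
    """Tie-dropping Kendall tau over all N(N-1)/2 unordered pairs.

    O(N log N) via the sort-and-count-inversions decomposition; exact
    integer pair counts, guaranteed identical to the brute-force pair scan.
    """
    x = list(x)
    y = list(y)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 items")
    pairs = sorted(zip(x, y))
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    n0 = n * (n - 1) // 2
    n1 = _tie_pairs(xs)                 # pairs tied in x
    n2 = _tie_pairs(sorted(y))          # pairs tied in y
    n3 = _tie_pairs(pairs)              # pairs tied in both
    # after sorting by (x, y), x-tie groups are y-sorted and contribute no
    # inversions, so every strict y-inversion is exactly a discordant pair
    discordant = _merge_count_inversions(ys)
    comparable = n0 - n1 - n2 + n3      # pairs untied in both coordinates
    concordant = comparable - discordant
    tau = (concordant - discordant) / n0
    return RankCorrelation(tau=tau, concordant=concordant, discordant=discordant, n_items=n)


def closeness(network: Network) -> dict:
    """C(i) = 1 / sum of geodesic distances from i to its reachable peers.

    Nodes with no reachable peer get 0.  On a disconnected network values
    from different components are not mutually comparable; a warning is
    logged.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not network.directed and g.number_of_nodes() > 1 and not nx.is_connected(g):
        logger.warning("network is disconnected; closeness restricted to reachable nodes")
    out = {}
    for node in g:
        dist = nx.single_source_shortest_path_length(g, node)
        total = sum(dist.values())
        if total == 0:
            logger.warning("node %r has no reachable peers; closeness set to 0", node)
            out[node] = 0.0
        else:
            out[node] = 1.0 / total
    return out


def betweenness(network: Network) -> dict:
    """Unnormalized betweenness B(i) = sum over unordered pairs s<t (both
    distinct from i) of the fraction of s-t geodesics passing through i."""
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    return {n: float(v) for n, v in
            nx.betweenness_centrality(network.graph, normalized=False).items()}


def correlation_report(
    network: Network,
    influence: InfluenceTable,
    centralities: dict,
) -> pd.DataFrame:
    """Kendall tau of each centrality against the influence table.

    ``centralities`` maps a display name to a node -> value mapping (or an
    :class:`HIndexTable`, which expands to one row per order h^(0)..h^(n_inf)).
    Returns one row per centrality with tau and the pair counts; the row
    with the highest tau is flagged ``best``.  The spreading settings are
    attached as ``DataFrame.attrs['config']``.
    """
    node_order = list(network.graph.nodes)
    inf_nodes = set(influence.influence)
    if inf_nodes != set(node_order):
        diff = inf_nodes.symmetric_difference(node_order)
        raise ValueError(f"influence/network node sets differ on {sorted(map(str, diff))[:5]}")
    expanded: list[tuple[str, dict]] = []
    for name, vals in centralities.items():
        if isinstance(vals, HIndexTable):
            for k in range(vals.n_inf + 1):
                expanded.append((f"{name}h({k})" if name else f"h({k})", vals.order(k)))
        else:
            expanded.append((name, vals))
    rows = []
    r = [influence.influence[n] for n in node_order]
    for name, vals in expanded:
        if set(vals) != set(node_order):
            raise ValueError(f"centrality {name!r} does not cover the network's node set")
        rc = kendall_tau([vals[n] for n in node_order], r)
        rows.append({"centrality": name, "tau": rc.tau,
                     "concordant": rc.concordant, "discordant": rc.discordant})
    df = pd.DataFrame(rows)
    df["best"] = df["tau"] == df["tau"].max()
    df.attrs["config"] = influence.config
    return df
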