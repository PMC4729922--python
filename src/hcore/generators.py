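"""Synthetic networks: canonical fixtures, hierarchical trees, random graphs.

The hierarchical tree is the star-of-stars construction in which influence
is encoded by level rather than degree: the two-level tree is a star with L
leaves, and each growth step turns every leaf into the centre of a new
L-leaf star (keeping its old link), adding one level.  All its nodes have
coreness 1, yet the H-index family (h^(0), ..., h^(D-2)) separates the
levels — the canonical example of why the intermediate family members carry
information that neither degree nor coreness does.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import Network

__all__ = ["TreeSpec", "hierarchical_tree", "canonical_graphs", "random_graph"]


@dataclass
class TreeSpec:
    """Hierarchical-tree parameters: L leaves per star, D >= 2 levels."""

    branching: int = 4
    levels: int = 2

    def __post_init__(self) -> None:
        if self.branching < 2:
            raise ValueError("branching must be >= 2")
        if self.levels < 2:
            raise ValueError("levels must be >= 2 (level 2 is the plain star)")

    @property
    def n_nodes(self) -> int:
        L, D = self.branching, self.levels
        return 1 + L * (L ** (D - 1) - 1) // (L - 1)


def hierarchical_tree(spec: TreeSpec) -> Network:
    """Build the D-level tree; each node carries its ``level`` attribute.

    Level 1 is the root; level ell >= 2 holds L^(ell-1) nodes.  The result
    is connected and acyclic with |E| = |V| - 1.
    """
    g = nx.Graph()
    root = "n0"
    g.add_node(root, level=1)
    frontier = [root]
    counter = 1
    for level in range(2, spec.levels + 1):
        next_frontier = []
        for parent in frontier:
            for _ in range(spec.branching):
                child = f"n{counter}"
                counter += 1
                g.add_node(child, level=level)
                g.add_edge(parent, child)
                next_frontier.append(child)
        frontier = next_frontier
    return Network(g)


def canonical_graphs(kind: str, size: int) -> Network:
    """Closed-form fixtures with deterministic string labels.

    ``star``: ``size`` leaves around centre "0" (size >= 1);
    ``complete``: K_size (size >= 1); ``path``: size nodes in a line
    (size >= 2); ``cycle``: C_size (size >= 3).
    """
    if kind == "star":
        if size < 1:
            raise ValueError("star needs >= 1 leaf")
        g = nx.star_graph(size)
    elif kind == "complete":
        if size < 1:
            raise ValueError("complete graph needs >= 1 node")
        g = nx.complete_graph(size)
    elif kind == "path":
        if size < 2:
            raise ValueError("path needs >= 2 nodes")
        g = nx.path_graph(size)
    elif kind == "cycle":
        if size < 3:
            raise ValueError("cycle needs >= 3 nodes")
        g = nx.cycle_graph(size)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return Network(nx.relabel_nodes(g, {n: str(n) for n in g.nodes}))


def random_graph(model: str, seed: int, **params) -> Network:
    """Seeded random test graphs.

    ``er``: Erdős–Rényi G(n, p) — params ``n``, ``p``.
    ``ba``: preferential attachment — params ``n``, ``m``: start from the
    complete graph K_m, then each arriving node links to ``m`` distinct
    existing nodes sampled proportionally to degree without replacement
    (edge count: C(m, 2) + (n - m) * m).
    """
    if model == "er":
        n, p = int(params["n"]), float(params["p"])
        if n < 1 or not 0.0 <= p <= 1.0:
            raise ValueError(f"invalid ER parameters n={n}, p={p}")
        g = nx.gnp_random_graph(n, p, seed=int(seed))
    elif model == "ba":
        n, m = int(params["n"]), int(params["m"])
        if m < 1 or n <= m:
            raise ValueError(f"invalid BA parameters n={n}, m={m} (need n > m >= 1)")
        rng = np.random.default_rng(seed)
        g = nx.complete_graph(m)
        degree = np.zeros(n, dtype=float)
        degree[:m] = m - 1
        for new in range(m, n):
            existing = np.arange(new)
            weights = degree[:new].copy()
            if weights.sum() == 0:
                weights[:] = 1.0
            targets: list[int] = []
            while len(targets) < m:
                probs = weights / weights.sum()
                t = int(rng.choice(existing, p=probs))
                targets.append(t)
                weights[t] = 0.0  # without replacement
            for t in targets:
                g.add_edge(new, t)
                degree[t] += 1
                degree[new] += 1
    else:
        raise ValueError(f"unknown model {model!r}")
    return Network(nx.relabel_nodes(g, {v: str(v) for v in g.nodes}))
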