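"""The H operator and the synchronous H-index family.

The operator :func:`h_operator` acts on a finite multiset of reals and
returns the largest integer ``y`` such that at least ``y`` elements are
``>= y``.  Applied to a node's neighbours' degrees it yields the node's
H-index; iterating it synchronously over the whole network produces the
family ``h^(0) = degree, h^(1) = H-index, ..., h^(n_inf) = coreness``.
The convergence of this iteration to the k-core shell index is exact and
guaranteed on finite simple graphs, which the test suite checks against an
independent pruning decomposition.

Also here: the resolution-rate and information-coverage diagnostics that
quantify how distinguishable and how local each member of the family is.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from math import comb

import networkx as nx

from .graph_core import Network, shortest_path_lengths

__all__ = [
    "h_operator",
    "weighted_h_operator",
    "HIndexTable",
    "synchronous_h_family",
    "variant_h_family",
    "resolution_rate",
    "information_coverage",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Iteration hit the order cap before reaching its fixed point.

    By construction the synchronous iteration always converges on a finite
    simple graph, so seeing this error signals an implementation bug (or a
    cap set below the true convergence time).
    """


def h_operator(values) -> int:
    """Largest integer ``y`` with at least ``y`` elements of ``values >= y``.

    Permutation-invariant; the empty sequence maps to 0; the result never
    exceeds ``len(values)``.  Elements may be arbitrary reals.
    """
    xs = []
    for x in values:
        if isinstance(x, bool) or not isinstance(x, numbers.Real):
            raise ValueError(f"non-numeric element {x!r}")
        xs.append(x)
    xs.sort(reverse=True)
    h = 0
    for i, x in enumerate(xs):
        if x >= i + 1:
            h = i + 1
        else:
            break
    return h


def weighted_h_operator(weights, values) -> int:
    """Weighted analogue: largest integer ``y`` such that the total weight
    attached to elements ``>= y`` is at least ``y``.

    With unit weights this reduces exactly to :func:`h_operator`.  Used by
    the weighted H-index family, where a neighbour counts with the weight of
    the connecting edge rather than as a single unit.
    """
    pairs = sorted(zip(values, weights), reverse=True)
    h = 0
    cum = 0.0
    for v, w in pairs:
        cum += w
        # all elements so far are >= v; candidate y is min(floor(cum), floor(v))
        y = min(int(cum), int(v))
        if y > h:
            h = y
    return h


@dataclass
class HIndexTable:
    """Per-node H-index sequences ``h^(0) ... h^(n_inf)`` plus n_inf.

    ``orders[node]`` is the full (nonincreasing) trajectory of node values;
    all trajectories have length ``n_inf + 1``.  ``h^(0)`` is the degree
    (or in-/out-degree/strength for the variants) and ``h^(n_inf)`` the
    coreness fixed point.
    """

    orders: dict
    n_inf: int
    mode: str = "undirected"

    def order(self, n: int) -> dict:
        """Node -> ``h^(n)``; orders beyond ``n_inf`` return the fixed point."""
        if n < 0:
            raise ValueError("order must be >= 0")
        idx = min(n, self.n_inf)
        return {node: seq[idx] for node, seq in self.orders.items()}

    @property
    def degree_map(self) -> dict:
        return self.order(0)

    @property
    def coreness(self) -> dict:
        return self.order(self.n_inf)


def _seed_and_neighbors(network: Network, mode: str):
    """Initial values and the neighbour function for each family variant."""
    g = network.graph
    if mode == "undirected":
        if network.directed:
            raise ValueError("undirected mode needs an undirected network")
        seed = {n: d for n, d in g.degree()}
        nbrs = lambda n: g.neighbors(n)  # noqa: E731
    elif mode == "in":
        if not network.directed:
            raise ValueError("in mode needs a directed network")
        seed = {n: d for n, d in g.in_degree()}
        nbrs = lambda n: g.predecessors(n)  # noqa: E731
    elif mode == "out":
        if not network.directed:
            raise ValueError("out mode needs a directed network")
        seed = {n: d for n, d in g.out_degree()}
        nbrs = lambda n: g.successors(n)  # noqa: E731
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return seed, nbrs


def synchronous_h_family(network: Network, max_order: int | None = None) -> HIndexTable:
    """Iterate the H operator synchronously until the coreness fixed point.

    Every sweep recomputes all nodes from the same previous-order snapshot.
    Iteration stops at the first sweep that changes nothing; ``n_inf`` is the
    number of sweeps that did change something (0 when degrees are already
    the fixed point, e.g. on regular graphs).
    """
    return _iterate(network, "undirected", max_order)


def variant_h_family(network: Network, mode: str, max_order: int | None = None) -> HIndexTable:
    """Directed (``in``/``out``) and ``weighted`` H-index families.

    ``in`` replaces degree by in-degree and neighbours by in-neighbours
    throughout (``out`` symmetric).  ``weighted`` seeds with node strength
    and iterates :func:`weighted_h_operator`, so each neighbour counts with
    its edge weight.  Fixed points match the correspondingly generalised
    pruning decompositions (see :mod:`hcore.coreness`).
    """
    if mode == "weighted":
        if not network.weighted:
            raise ValueError("weighted mode needs a weighted network")
        if network.directed:
            raise ValueError("weighted mode is defined for undirected networks")
        return _iterate_weighted(network, max_order)
    return _iterate(network, mode, max_order)


def _iterate(network: Network, mode: str, max_order: int | None) -> HIndexTable:
    seed, nbrs = _seed_and_neighbors(network, mode)
    orders = {n: [v] for n, v in seed.items()}
    current = dict(seed)
    sweep = 0
    while True:
        nxt = {n: h_operator([current[j] for j in nbrs(n)]) for n in current}
        if nxt == current:
            return HIndexTable(orders=orders, n_inf=sweep, mode=mode)
        sweep += 1
        if max_order is not None and sweep > max_order:
            raise ConvergenceError(f"no fixed point within max_order={max_order}")
        for n, v in nxt.items():
            orders[n].append(v)
        current = nxt


def _iterate_weighted(network: Network, max_order: int | None) -> HIndexTable:
    g = network.graph
    current = {n: network.strength(n) for n in g}
    orders = {n: [v] for n, v in current.items()}
    sweep = 0
    while True:
        nxt = {}
        for n in current:
            ws, vs = [], []
            for j in g.neighbors(n):
                ws.append(g[n][j]["weight"])
                vs.append(current[j])
            nxt[n] = weighted_h_operator(ws, vs)
        if nxt == current:
            return HIndexTable(orders=orders, n_inf=sweep, mode="weighted")
        sweep += 1
        if max_order is not None and sweep > max_order:
            raise ConvergenceError(f"no fixed point within max_order={max_order}")
        for n, v in nxt.items():
            orders[n].append(v)
        current = nxt


def resolution_rate(values) -> float:
    """Probability that two distinct randomly chosen nodes differ in value.

    ``values`` is a node -> value mapping (or a plain sequence).  Computed
    over unordered distinct pairs: ``1 - sum_c C(m_c, 2) / C(N, 2)`` where
    ``m_c`` are the multiplicities of each distinct value.
    """
    vals = list(values.values()) if hasattr(values, "values") else list(values)
    n = len(vals)
    if n < 2:
        raise ValueError("resolution rate needs at least 2 nodes")
    counts: dict = {}
    for v in vals:
        counts[v] = counts.get(v, 0) + 1
    tied = sum(comb(m, 2) for m in counts.values())
    return 1.0 - tied / comb(n, 2)


def information_coverage(network: Network, node, n: int) -> float:
    """Fraction of the network within hop distance ``n`` of ``node``.

    Measures how much of the topology the ``n``-order index can draw on;
    the node itself (distance 0) is always counted, so the result is in
    ``(0, 1]``.
    """
    if n < 0:
        raise ValueError("order must be >= 0")
    dist = shortest_path_lengths(network, node)
    ball = sum(1 for d in dist.values() if d <= n)
    return ball / network.n_nodes
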