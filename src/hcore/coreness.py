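"""k-core decomposition and the asynchronous decentralized coreness updater.

:func:`coreness_by_pruning` is the classic shell-peeling decomposition,
implemented with a bucket queue in O(|E|).  It serves as the independent
oracle for the H-index iteration: the synchronous family's fixed point and
the asynchronous updater's steady state must both equal it exactly.

:func:`asynchronous_coreness` starts every node at its degree and applies
the H operator to one node at a time, each update reading its neighbours'
*current* values (no global clock).  The process provably reaches the
coreness fixed point from above regardless of the update schedule, which
makes a decentralized, resumable computation possible — including on
growing networks (:func:`resume_after_edge_addition`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_core import Network
from .h_family import h_operator

__all__ = [
    "CorenessTable",
    "AsyncState",
    "coreness_by_pruning",
    "directed_coreness_by_pruning",
    "weighted_coreness_by_pruning",
    "asynchronous_coreness",
    "verify_steady_state",
    "resume_after_edge_addition",
]


@dataclass
class CorenessTable:
    """Node -> shell index c_i, plus the largest k with a nonempty k-core."""

    coreness: dict
    max_core: int


@dataclass
class AsyncState:
    """State of an asynchronous coreness run.

    ``g`` maps each node to its current value (degree at start, coreness at
    the steady state); ``updates`` counts operator applications that were
    scheduled (verification passes are not counted); ``history`` optionally
    traces every value a node has taken, which is nonincreasing and never
    drops below the true coreness.
    """

    g: dict
    updates: int
    rng_seed: int
    schedule: str = "uniform"
    steady: bool = False
    history: dict | None = None


def coreness_by_pruning(network: Network) -> CorenessTable:
    """Shell-peeling k-core decomposition (bucket queue, O(|E|)).

    Peels nodes in nondecreasing order of current degree: while the minimum
    remaining degree is <= k the peeled node joins the k-shell, and k only
    ever grows.  Isolated nodes get coreness 0.
    """
    g = network.graph
    if network.directed:
        raise ValueError("use directed_coreness_by_pruning for directed networks")
    deg = {n: d for n, d in g.degree()}
    if not deg:
        return CorenessTable(coreness={}, max_core=0)
    max_deg = max(deg.values())
    # bucket queue: bins[d] holds nodes of current degree d
    bins: list[list] = [[] for _ in range(max_deg + 1)]
    for n, d in deg.items():
        bins[d].append(n)
    core: dict = {}
    k = 0
    d = 0
    remaining = len(deg)
    while remaining:
        while not bins[d]:
            d += 1
        node = bins[d].pop()
        if node in core:
            continue  # stale bucket entry
        k = max(k, d)
        core[node] = k
        remaining -= 1
        for nb in g.neighbors(node):
            if nb in core:
                continue
            deg[nb] -= 1
            bins[deg[nb]].append(nb)
            if deg[nb] < d:
                d = deg[nb]
    return CorenessTable(coreness=core, max_core=max(core.values(), default=0))


def directed_coreness_by_pruning(network: Network, mode: str) -> CorenessTable:
    """In- or out-coreness: peel by in-degree (resp. out-degree).

    Removing a node lowers the in-degree of its successors (out-degree of
    its predecessors), so the peeling cascades along the opposite direction
    of the pruned quantity.
    """
    if not network.directed:
        raise ValueError("directed pruning needs a directed network")
    g = network.graph
    if mode == "in":
        deg = {n: d for n, d in g.in_degree()}
        affected = lambda n: g.successors(n)  # noqa: E731
    elif mode == "out":
        deg = {n: d for n, d in g.out_degree()}
        affected = lambda n: g.predecessors(n)  # noqa: E731
    else:
        raise ValueError(f"unknown mode {mode!r}")
    core: dict = {}
    k = 0
    alive = set(deg)
    while alive:
        k_level = min(deg[n] for n in alive)
        k = max(k, k_level)
        queue = [n for n in alive if deg[n] <= k]
        while queue:
            node = queue.pop()
            if node not in alive:
                continue
            alive.discard(node)
            core[node] = k
            for nb in affected(node):
                if nb in alive:
                    deg[nb] -= 1
                    if deg[nb] <= k:
                        queue.append(nb)
    return CorenessTable(coreness=core, max_core=max(core.values(), default=0))


def weighted_coreness_by_pruning(network: Network) -> CorenessTable:
    """Integer strength-threshold decomposition.

    Node i gets c_i = the largest integer s such that i survives iterative
    removal of all nodes whose remaining strength (sum of incident weights)
    is below s.  With unit weights this is exactly the unweighted k-core
    decomposition.
    """
    if not network.weighted:
        raise ValueError("weighted pruning needs a weighted network")
    g = network.graph
    strength = {n: float(g.degree(n, weight="weight")) for n in g}
    core: dict = {}
    alive = set(strength)
    s = 0
    while alive:
        # jump past empty levels: nothing is removed until s reaches the
        # floor of the minimum remaining strength
        s = max(s, int(min(strength[n] for n in alive)))
        # remove everything that cannot sustain strength >= s + 1 at level s
        queue = [n for n in alive if strength[n] < s + 1]
        while queue:
            node = queue.pop()
            if node not in alive:
                continue
            alive.discard(node)
            core[node] = s
            for nb in g.neighbors(node):
                if nb in alive:
                    strength[nb] -= g[node][nb]["weight"]
                    if strength[nb] < s + 1:
                        queue.append(nb)
        s += 1
    return CorenessTable(coreness=core, max_core=max(core.values(), default=0))


def _neighbor_update(g, values, node) -> int:
    return h_operator([values[j] for j in g.neighbors(node)])


def verify_steady_state(network: Network, g_values: dict) -> bool:
    """True iff applying the operator at every node leaves every value fixed."""
    graph = network.graph
    missing = [n for n in graph if n not in g_values]
    if missing:
        raise ValueError(f"g undefined for node(s) {missing[:3]}")
    return all(_neighbor_update(graph, g_values, n) == g_values[n] for n in graph)


def _make_scheduler(network: Network, schedule, rng: np.random.Generator):
    """Return a callable yielding the next node to update.

    Built-ins: ``uniform`` (seeded random choice), ``round_robin``
    (deterministic cyclic order), ``stalest_first`` (always the node whose
    value is oldest, ties broken by label order).  A custom callable
    ``schedule(g, last_update) -> node`` may be supplied instead.
    """
    nodes = sorted(network.graph.nodes, key=str)
    if callable(schedule):
        return schedule
    if schedule == "uniform":
        def pick(g, last_update):
            return nodes[rng.integers(len(nodes))]
        return pick
    if schedule == "round_robin":
        state = {"i": 0}
        def pick(g, last_update):
            node = nodes[state["i"] % len(nodes)]
            state["i"] += 1
            return node
        return pick
    if schedule == "stalest_first":
        def pick(g, last_update):
            return min(nodes, key=lambda n: (last_update[n], str(n)))
        return pick
    raise ValueError(f"unknown schedule {schedule!r}")


def _run_async(
    network: Network,
    g: dict,
    seed: int,
    schedule,
    track_history: bool,
    updates: int = 0,
) -> AsyncState:
    graph = network.graph
    n = graph.number_of_nodes()
    name = schedule if isinstance(schedule, str) else getattr(schedule, "__name__", "custom")
    history = {node: [g[node]] for node in graph} if track_history else None
    if n == 0:
        return AsyncState(g=dict(g), updates=updates, rng_seed=seed,
                          schedule=name, steady=True, history=history)
    rng = np.random.default_rng(seed)
    pick = _make_scheduler(network, schedule, rng)
    last_update = {node: 0 for node in graph}
    clock = 0
    # safety cap: the monotone decrease bounds true work by sum(degrees);
    # the cap is far above that and only trips on an implementation bug
    cap = 1000 * (n + sum(d for _, d in graph.degree()) + 1)
    sweeps = 0
    while True:
        for _ in range(n):
            node = pick(g, last_update)
            clock += 1
            last_update[node] = clock
            new = _neighbor_update(graph, g, node)
            updates += 1
            if new != g[node]:
                g[node] = new
                if history is not None:
                    history[node].append(new)
        if verify_steady_state(network, g):
            return AsyncState(g=dict(g), updates=updates, rng_seed=seed,
                              schedule=name, steady=True, history=history)
        sweeps += 1
        if sweeps * n > cap:
            raise RuntimeError("asynchronous updating failed to converge (bug)")


def asynchronous_coreness(
    network: Network,
    seed: int,
    schedule="uniform",
    track_history: bool = False,
) -> AsyncState:
    """Compute coreness by asynchronous one-node-at-a-time updates.

    Every node starts at its degree; each scheduled update replaces a node's
    value by the H operator applied to its neighbours' current values.
    After every |V| scheduled updates a deterministic verification pass
    checks the steady-state condition (no node's update would change its
    value); termination is therefore exact, not probabilistic.  The steady
    state equals the pruning coreness for every node.
    """
    if network.directed:
        raise ValueError("asynchronous coreness is defined for undirected networks")
    g = {node: d for node, d in network.graph.degree()}
    return _run_async(network, g, seed, schedule, track_history)


def resume_after_edge_addition(
    network: Network,
    g: dict,
    new_edges,
    seed: int,
    schedule="uniform",
    track_history: bool = False,
) -> AsyncState:
    """Resume a converged asynchronous run after adding edges.

    ``network`` is modified in place: the new edges (and any new nodes) are
    inserted.  The asynchronous process converges from above only, so the
    g >= coreness invariant must be restored wherever an insertion can raise
    coreness.  A new edge (u, v) can raise coreness only for nodes in shell
    k = min(g_u, g_v) reachable from the endpoints through nodes of shell
    <= k, and only by 1; that region is bumped to k + 1, the endpoints are
    reset to their new degree, and the updating resumes (per edge, so each
    region is computed from exact coreness values).  Everything outside the
    region keeps its old g — the locality that makes the decentralized
    algorithm usable on growing networks.
    """
    graph = network.graph
    g = dict(g)
    missing = [n for n in graph if n not in g]
    if missing:
        raise ValueError(f"g undefined for node(s) {missing[:3]}")
    if not verify_steady_state(network, g):
        raise ValueError("g is not a steady state of the pre-addition network")
    total_updates = 0
    history = {node: [g[node]] for node in graph} if track_history else None
    state = AsyncState(g=dict(g), updates=0, rng_seed=seed, steady=True,
                       schedule=schedule if isinstance(schedule, str) else "custom",
                       history=history)
    for edge_i, (u, v) in enumerate(tuple(e) for e in new_edges):
        if u == v:
            raise ValueError(f"self-loop ({u}, {v}) not allowed")
        if graph.has_edge(u, v):
            continue
        for w in (u, v):
            if w not in graph:
                graph.add_node(w)
                g[w] = 0  # new node: empty neighbourhood so far
                if history is not None:
                    history[w] = []
        graph.add_edge(u, v)
        k = min(g[u], g[v])
        # bump the affected shell-k region reachable through shells <= k
        stack, seen = [u, v], {u, v}
        while stack:
            node = stack.pop()
            if g[node] <= k:
                g[node] = k + 1
            for nb in graph.neighbors(node):
                if nb not in seen and g[nb] <= k:
                    seen.add(nb)
                    stack.append(nb)
        g[u] = graph.degree(u)
        g[v] = graph.degree(v)
        state = _run_async(network, g, seed + edge_i, schedule, False)
        g = state.g
        if history is not None:
            for node, value in g.items():
                if not history[node] or history[node][-1] != value:
                    history[node].append(value)
        total_updates += state.updates
    state.updates = total_updates
    state.history = history
    state.rng_seed = seed
    return state
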