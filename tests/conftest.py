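"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities by exhaustive definition
(candidate scans, literal shell peeling, all-pairs enumeration) so the fast
implementations are checked against something that cannot share their bugs.
"""

from __future__ import annotations

import networkx as nx
import pytest

from hcore import Network, canonical_graphs, hierarchical_tree, random_graph, TreeSpec


# --------------------------------------------------------------------------
# oracles

def brute_h(values) -> int:
    """Definition scan: largest y in 0..len with at least y elements >= y."""
    vals = list(values)
    best = 0
    for y in range(len(vals) + 1):
        if sum(1 for v in vals if v >= y) >= y:
            best = y
    return best


def brute_weighted_h(weights, values) -> int:
    """Definition scan for the weighted operator: largest integer y with
    total weight on elements >= y at least y."""
    total = int(sum(weights)) + 1
    best = 0
    for y in range(total + 1):
        if sum(w for w, v in zip(weights, values) if v >= y) >= y:
            best = y
    return best


def peel_coreness(graph: nx.Graph) -> dict:
    """Literal shell peeling: for k = 0, 1, 2, ... repeatedly delete every
    node of current degree <= k, assigning it coreness k."""
    g = graph.copy()
    core: dict = {}
    k = 0
    while g.number_of_nodes():
        victims = [n for n, d in g.degree() if d <= k]
        if not victims:
            k += 1
            continue
        for n in victims:
            core[n] = k
        g.remove_nodes_from(victims)
    return core


def brute_tau(x, y):
    """O(N^2) pair scan of the tie-dropping Kendall tau."""
    n = len(x)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = (x[i] > x[j]) - (x[i] < x[j])
            dy = (y[i] > y[j]) - (y[i] < y[j])
            if dx * dy > 0:
                conc += 1
            elif dx * dy < 0:
                disc += 1
    return (conc - disc) / (n * (n - 1) // 2), conc, disc


# --------------------------------------------------------------------------
# fixtures

@pytest.fixture
def star4() -> Network:
    """Star with 4 leaves; centre is node '0'."""
    return canonical_graphs("star", 4)


@pytest.fixture
def k5() -> Network:
    return canonical_graphs("complete", 5)


@pytest.fixture
def path3() -> Network:
    return canonical_graphs("path", 3)


@pytest.fixture
def tree_l4_d4() -> Network:
    return hierarchical_tree(TreeSpec(branching=4, levels=4))


@pytest.fixture(scope="session")
def small_random_corpus() -> list[Network]:
    """20 ER + 5 preferential-attachment graphs for property checks."""
    nets = [random_graph("er", seed=s, n=60, p=0.06) for s in range(20)]
    nets += [random_graph("ba", seed=s, n=80, m=3) for s in range(5)]
    return nets
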