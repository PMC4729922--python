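"""H operator, synchronous family, diagnostics, directed/weighted variants."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcore import (
    ConvergenceError,
    Network,
    canonical_graphs,
    coreness_by_pruning,
    directed_coreness_by_pruning,
    h_operator,
    hierarchical_tree,
    information_coverage,
    random_graph,
    resolution_rate,
    synchronous_h_family,
    TreeSpec,
    variant_h_family,
    weighted_coreness_by_pruning,
    weighted_h_operator,
)
from conftest import brute_h, brute_weighted_h


# --------------------------------------------------------------------------
# the operator

@pytest.mark.parametrize(
    "values,expected",
    [
        ([], 0),
        ([3, 3, 3], 3),
        ([4, 1, 4, 2, 4], 3),
        ([0.5, 0.5], 0),
        ([10], 1),
        ([0, 0, 0], 0),
    ],
)
def test_h_operator_examples(values, expected):
    assert h_operator(values) == expected


def test_h_operator_rejects_non_numeric():
    with pytest.raises(ValueError):
        h_operator([1, "two", 3])


@settings(derandomize=True, max_examples=300)
@given(st.lists(st.floats(min_value=-5, max_value=50, allow_nan=False), max_size=25))
def test_h_operator_matches_brute_force(values):
    res = h_operator(values)
    assert res == brute_h(values)
    assert 0 <= res <= len(values)


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(min_value=-5, max_value=50, allow_nan=False), max_size=15),
       st.randoms(use_true_random=False))
def test_h_operator_permutation_invariant(values, rnd):
    shuffled = list(values)
    rnd.shuffle(shuffled)
    assert h_operator(shuffled) == h_operator(values)


# weights/values on the binary-exact half-integer grid so the cumulative
# sums in the fast path and the subset sums in the oracle agree bit-for-bit
@settings(derandomize=True, max_examples=200)
@given(st.lists(st.tuples(st.integers(1, 16).map(lambda i: i / 2),
                          st.integers(0, 40).map(lambda i: i / 2)), max_size=12))
def test_weighted_h_operator_matches_brute_force(pairs):
    ws = [w for w, _ in pairs]
    vs = [v for _, v in pairs]
    assert weighted_h_operator(ws, vs) == brute_weighted_h(ws, vs)


def test_weighted_h_operator_unit_weights_reduce_to_plain():
    vals = [4, 1, 4, 2, 4]
    assert weighted_h_operator([1] * 5, vals) == h_operator(vals)


# --------------------------------------------------------------------------
# synchronous family

def test_family_star(star4):
    t = synchronous_h_family(star4)
    assert t.n_inf == 1
    assert t.orders["0"] == [4, 1]
    for leaf in "1234":
        assert t.orders[leaf] == [1, 1]


def test_family_regular_graph_converges_immediately(k5):
    t = synchronous_h_family(k5)
    assert t.n_inf == 0
    assert all(seq == [4] for seq in t.orders.values())


def test_family_rejects_directed():
    net = Network(nx.DiGraph([("a", "b")]))
    with pytest.raises(ValueError):
        synchronous_h_family(net)


def test_max_order_cap_raises(star4):
    with pytest.raises(ConvergenceError):
        synchronous_h_family(star4, max_order=0)


def test_family_properties_on_random_corpus(small_random_corpus):
    """Monotone nonincreasing sequences, degree start, pruning fixed point,
    k_min lower bound — on every random graph."""
    for net in small_random_corpus:
        t = synchronous_h_family(net)
        oracle = coreness_by_pruning(net).coreness
        k_min = min(d for _, d in net.graph.degree())
        for node, seq in t.orders.items():
            assert seq[0] == net.graph.degree(node)
            assert all(a >= b for a, b in zip(seq, seq[1:]))
            assert seq[-1] == oracle[node]
            assert all(v >= k_min for v in seq)
            assert all(v <= net.graph.degree(node) for v in seq)


def test_family_subgraph_monotonicity():
    """h^(n) computed in an induced subgraph never exceeds h^(n) in the
    full graph, for all overlapping nodes and orders."""
    for seed in range(5):
        net = random_graph("er", seed=seed, n=50, p=0.1)
        keep = [n for n in net.graph.nodes if int(n) % 3 != 0]
        sub = Network(net.graph.subgraph(keep).copy())
        tg = synchronous_h_family(net)
        ts = synchronous_h_family(sub)
        depth = min(tg.n_inf, ts.n_inf)
        for node in sub.graph.nodes:
            for n_order in range(depth + 1):
                assert ts.order(n_order)[node] <= tg.order(n_order)[node]


def test_family_levels_identical_in_hierarchical_tree(tree_l4_d4):
    t = synchronous_h_family(tree_l4_d4)
    levels = nx.get_node_attributes(tree_l4_d4.graph, "level")
    by_level: dict = {}
    for node, seq in t.orders.items():
        by_level.setdefault(levels[node], set()).add(tuple(seq))
    assert all(len(v) == 1 for v in by_level.values())


# --------------------------------------------------------------------------
# diagnostics

@pytest.mark.parametrize(
    "values,expected",
    [([1, 2, 3], 1.0), ([7, 7, 7], 0.0), ([1, 1, 2], 2 / 3)],
)
def test_resolution_rate(values, expected):
    assert resolution_rate(values) == pytest.approx(expected)


def test_resolution_rate_needs_two_nodes():
    with pytest.raises(ValueError):
        resolution_rate([1])


def test_resolution_matches_pair_enumeration():
    import itertools

    vals = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3]
    pairs = list(itertools.combinations(vals, 2))
    expected = sum(a != b for a, b in pairs) / len(pairs)
    assert resolution_rate(vals) == pytest.approx(expected)


def test_degree_is_most_distinguishable(small_random_corpus):
    # the family coarse-grains: h^(0) resolves best and coreness resolves
    # strictly worse (intermediate orders need not be monotone)
    for net in small_random_corpus[:6]:
        t = synchronous_h_family(net)
        rates = [resolution_rate(t.order(n)) for n in range(t.n_inf + 1)]
        assert rates[0] == max(rates)
        assert rates[-1] < rates[0]


def test_information_coverage_star(star4):
    assert information_coverage(star4, "0", 1) == 1.0
    assert information_coverage(star4, "1", 1) == pytest.approx(2 / 5)
    assert information_coverage(star4, "1", 2) == 1.0
    with pytest.raises(KeyError):
        information_coverage(star4, "zzz", 1)


def test_information_coverage_monotone_in_order(tree_l4_d4):
    node = "n1"
    cov = [information_coverage(tree_l4_d4, node, n) for n in range(7)]
    assert all(a <= b for a, b in zip(cov, cov[1:]))
    assert cov[6] == 1.0  # beyond the eccentricity


# --------------------------------------------------------------------------
# directed / weighted variants

def test_variant_directed_cycle():
    g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
    t = variant_h_family(Network(g), "in")
    assert all(seq == [1] for seq in t.orders.values())


def test_variant_star_all_edges_inward():
    leaves = ["l1", "l2", "l3", "l4"]
    g = nx.DiGraph([(leaf, "c") for leaf in leaves])
    t = variant_h_family(Network(g), "in")
    assert t.order(0)["c"] == len(leaves)
    assert all(t.order(0)[leaf] == 0 for leaf in leaves)


@pytest.mark.parametrize("mode", ["in", "out"])
def test_variant_fixed_point_matches_directed_pruning(mode):
    for seed in range(6):
        g = nx.gnp_random_graph(40, 0.08, seed=seed, directed=True)
        net = Network(nx.relabel_nodes(g, str))
        t = variant_h_family(net, mode)
        oracle = directed_coreness_by_pruning(net, mode).coreness
        assert t.coreness == oracle


def test_variant_mode_network_mismatch(star4):
    with pytest.raises(ValueError):
        variant_h_family(star4, "in")
    with pytest.raises(ValueError):
        variant_h_family(star4, "weighted")


def test_weighted_family_unit_weights_match_plain():
    base = random_graph("er", seed=3, n=40, p=0.1)
    g = base.graph.copy()
    nx.set_edge_attributes(g, 1.0, "weight")
    plain = synchronous_h_family(base)
    weighted = variant_h_family(Network(g, weighted=True), "weighted")
    assert weighted.coreness == plain.coreness
    assert weighted.n_inf == plain.n_inf


def test_weighted_family_fixed_point_matches_strength_pruning():
    import numpy as np

    for seed in range(6):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(35, 0.12, seed=seed)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.integers(1, 5))
        net = Network(nx.relabel_nodes(g, str), weighted=True)
        t = variant_h_family(net, "weighted")
        oracle = weighted_coreness_by_pruning(net).coreness
        assert t.coreness == oracle
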