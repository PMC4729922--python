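"""Discrete-time SIR / SIS / bond-percolation influence simulators.

These define the ground truth the centralities are ranked against: the
spreading influence R_i of node i is, for SIR, the mean number of removed
nodes after an outbreak seeded solely at i; for SIS, the probability that i
is infected in the endemic steady state; for bond percolation, either the
probability that i joins the giant component or the mean size of its
component.

SIR uses synchronous generations with infection resolved before removal in
each step; with removal probability lam = 1 (the default) every node is
infectious for exactly one generation, the independent-cascade limit.
Spreading rates are conventionally quoted as multiples of the epidemic
threshold beta_c = <k> / (<k^2> - <k>) from heterogeneous mean-field
theory; influence rankings are measured at 1.5, 2 and 2.5 times beta_c,
where outbreaks stay small enough for the seed to matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .graph_core import Network

__all__ = [
    "SpreadingConfig",
    "InfluenceTable",
    "epidemic_threshold_hmf",
    "epidemic_threshold_simulated",
    "sir_influence",
    "sis_influence",
    "bond_percolation_influence",
]


@dataclass
class SpreadingConfig:
    """Simulation settings for the spreading models.

    beta : infection probability per infected-susceptible contact, in [0, 1]
    lam  : removal (SIR) / recovery (SIS) probability per step, in [0, 1]
    runs : Monte-Carlo repetitions per node (SIR) or per realization (SIS)
    rng_seed : master seed; SIR derives one stream per (seed, node, run)
    model : 'sir' | 'sis' | 'bond'
    """

    beta: float
    lam: float = 1.0
    runs: int = 1000
    rng_seed: int = 0
    model: str = "sir"

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.model not in ("sir", "sis", "bond"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class InfluenceTable:
    """Per-node influence R_i with the settings that produced it."""

    influence: dict
    config: SpreadingConfig
    stderr: dict | None = None
    meta: dict = field(default_factory=dict)


def _as_arrays(network: Network):
    """Stable node order, index map, and per-node neighbour index arrays."""
    nodes = list(network.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    adj = [np.fromiter((index[j] for j in network.graph.neighbors(n)), dtype=np.int64)
           for n in nodes]
    return nodes, index, adj


def _adjacency_csr(network: Network):
    nodes = list(network.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for u, v in network.graph.edges():
        iu, iv = index[u], index[v]
        rows += [iu, iv]
        cols += [iv, iu]
    data = np.ones(len(rows), dtype=np.int8)
    return nodes, csr_matrix((data, (rows, cols)), shape=(n, n))


def epidemic_threshold_hmf(network: Network) -> float:
    """Heterogeneous mean-field SIR threshold <k> / (<k^2> - <k>).

    Computed from the empirical degree moments; undefined (raises) when
    <k^2> <= <k>, e.g. when all degrees are 0 or 1.
    """
    degs = np.array([d for _, d in network.graph.degree()], dtype=float)
    if degs.size == 0 or network.n_edges == 0:
        raise ValueError("threshold needs a network with at least one edge")
    k1 = degs.mean()
    k2 = (degs**2).mean()
    if k2 - k1 <= 0:
        raise ValueError(f"degenerate degree moments: <k^2>={k2:g} <= <k>={k1:g}")
    return float(k1 / (k2 - k1))


def _sir_run(adj, n, seed_idx, beta, lam, rng) -> int:
    """One SIR outbreak; returns the final removed count."""
    if lam >= 1.0:
        # independent-cascade limit: one infectious generation per node
        touched = np.zeros(n, dtype=bool)
        touched[seed_idx] = True
        frontier = np.array([seed_idx], dtype=np.int64)
        size = 1
        while frontier.size:
            hits = []
            for u in frontier:
                cand = adj[u][~touched[adj[u]]]
                if cand.size:
                    hit = cand[rng.random(cand.size) < beta]
                    if hit.size:
                        touched[hit] = True
                        hits.append(hit)
            frontier = np.concatenate(hits) if hits else np.empty(0, dtype=np.int64)
            size += frontier.size
        return size
    status = np.zeros(n, dtype=np.int8)  # 0 susceptible, 1 infected, 2 removed
    status[seed_idx] = 1
    while True:
        infected = np.flatnonzero(status == 1)
        if infected.size == 0:
            return int((status == 2).sum())
        for u in infected:
            cand = adj[u][status[adj[u]] == 0]
            if cand.size:
                hit = cand[rng.random(cand.size) < beta]
                status[hit] = 1  # infectious from the next step on
        # removal draws apply to nodes infected before this step
        rem = infected[rng.random(infected.size) < lam]
        status[rem] = 2


def sir_influence(network: Network, config: SpreadingConfig) -> InfluenceTable:
    """SIR influence R_i: mean removed count over runs seeded at each node.

    One RNG stream per (master seed, node, run) keeps every node's result
    independent of evaluation order.
    """
    if config.model != "sir":
        raise ValueError("config.model must be 'sir'")
    nodes, _, adj = _as_arrays(network)
    n = len(nodes)
    influence, stderr = {}, {}
    for i, node in enumerate(nodes):
        sizes = np.empty(config.runs, dtype=float)
        for r in range(config.runs):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(i, r)))
            sizes[r] = _sir_run(adj, n, i, config.beta, config.lam, rng)
        influence[node] = float(sizes.mean())
        stderr[node] = float(sizes.std(ddof=1) / np.sqrt(config.runs)) if config.runs > 1 else 0.0
    return InfluenceTable(influence=influence, config=config, stderr=stderr)


def epidemic_threshold_simulated(
    network: Network,
    beta_grid,
    runs: int = 200,
    seed: int = 0,
) -> float:
    """Estimate beta_c as the grid point maximizing outbreak-size variability.

    At each beta, SIR outbreaks are started from uniformly random seeds and
    the susceptibility chi = (<s^2> - <s>^2) / <s> of the final size s is
    computed; the peak of chi locates the transition.
    """
    grid = [float(b) for b in beta_grid]
    if not grid:
        raise ValueError("beta grid is empty")
    if any(not 0.0 <= b <= 1.0 for b in grid):
        raise ValueError("beta grid must lie in [0, 1]")
    if sorted(grid) != grid:
        raise ValueError("beta grid must be sorted")
    nodes, _, adj = _as_arrays(network)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    chi = np.empty(len(grid))
    for b_i, beta in enumerate(grid):
        sizes = np.empty(runs, dtype=float)
        for r in range(runs):
            sizes[r] = _sir_run(adj, n, int(rng.integers(n)), beta, 1.0, rng)
        mean = sizes.mean()
        chi[b_i] = (sizes.var() / mean) if mean > 0 else 0.0
    return grid[int(np.argmax(chi))]


def sis_influence(
    network: Network,
    config: SpreadingConfig,
    t_transient: int = 100,
    t_sample: int = 100,
    max_restarts: int = 5,
) -> InfluenceTable:
    """SIS steady-state influence: P(node i infected) in the endemic state.

    Starts all-infected, discards ``t_transient`` steps, then averages each
    node's infection indicator over ``t_sample`` steps and ``config.runs``
    realizations.  A realization that falls into the absorbing all-
    susceptible state is restarted (up to ``max_restarts`` times); when
    restarts are exhausted — inevitable below threshold, and always at
    beta = 0 — the realization counts as all-zero and the table's metadata
    flags the die-out.
    """
    if config.model != "sis":
        raise ValueError("config.model must be 'sis'")
    if t_sample < 1:
        raise ValueError("t_sample must be >= 1")
    nodes, A = _adjacency_csr(network)
    n = len(nodes)
    beta, lam = config.beta, config.lam
    rng = np.random.default_rng(config.rng_seed)
    totals = np.zeros(n, dtype=float)
    absorbed = 0

    def _one_realization():
        state = np.ones(n, dtype=bool)
        acc = np.zeros(n, dtype=float)
        for t in range(t_transient + t_sample):
            m = A @ state  # infected-neighbour counts
            p_inf = 1.0 - (1.0 - beta) ** m
            infect = (~state) & (rng.random(n) < p_inf)
            stay = state & (rng.random(n) >= lam)
            state = stay | infect
            if not state.any():
                return None  # absorbed
            if t >= t_transient:
                acc += state
        return acc / t_sample

    for _ in range(config.runs):
        acc = None
        attempts = 0
        while acc is None and attempts <= max_restarts:
            if beta == 0.0 and attempts > 0:
                break  # restarting cannot help without infection
            acc = _one_realization()
            attempts += 1
        if acc is None:
            absorbed += 1
            acc = np.zeros(n, dtype=float)
        totals += acc
    mean = totals / config.runs
    meta = {"t_transient": t_transient, "t_sample": t_sample,
            "absorbed_runs": absorbed}
    return InfluenceTable(
        influence={node: float(mean[i]) for i, node in enumerate(nodes)},
        config=config,
        meta=meta,
    )


def bond_percolation_influence(
    network: Network,
    p: float,
    runs: int = 1000,
    mode: str = "giant_membership",
    seed: int = 0,
) -> InfluenceTable:
    """Bond-percolation influence at edge-occupation probability p.

    Each run keeps every edge independently with probability p.
    ``giant_membership``: fraction of runs in which the node lies in the
    largest component (size ties broken by the smallest component label, so
    runs are deterministic given the seed).  ``component_size``: mean size
    of the node's component.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if mode not in ("giant_membership", "component_size"):
        raise ValueError(f"unknown mode {mode!r}")
    nodes = list(network.graph.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    edges = np.array([(index[u], index[v]) for u, v in network.graph.edges()],
                     dtype=np.int64).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    totals = np.zeros(n, dtype=float)
    sq = np.zeros(n, dtype=float)
    for _ in range(runs):
        keep = edges[rng.random(len(edges)) < p] if len(edges) else edges
        data = np.ones(len(keep), dtype=np.int8)
        A = csr_matrix((data, (keep[:, 0], keep[:, 1])), shape=(n, n))
        _, labels = connected_components(A, directed=False)
        sizes = np.bincount(labels)
        if mode == "giant_membership":
            giant = int(np.argmax(sizes))  # first max -> smallest label
            val = (labels == giant).astype(float)
        else:
            val = sizes[labels].astype(float)
        totals += val
        sq += val * val
    mean = totals / runs
    var = np.maximum(sq / runs - mean**2, 0.0)
    se = np.sqrt(var / runs) * np.sqrt(runs / max(runs - 1, 1))
    config = SpreadingConfig(beta=p, lam=1.0, runs=runs, rng_seed=seed, model="bond")
    return InfluenceTable(
        influence={u: float(mean[i]) for i, u in enumerate(nodes)},
        config=config,
        stderr={u: float(se[i]) for i, u in enumerate(nodes)},
        meta={"mode": mode, "p": p},
    )
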