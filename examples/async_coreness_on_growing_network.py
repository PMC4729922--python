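"""Decentralized coreness, resumed as the network grows.

Runs the asynchronous updater (each step: one node recomputes its value
from its neighbours' current values — no global clock) on a random graph,
then inserts a handful of edges and resumes from the converged state
instead of recomputing from scratch.  After every insertion the resumed
values are checked against a fresh pruning decomposition.
"""

from hcore import asynchronous_coreness, coreness_by_pruning, random_graph, resume_after_edge_addition

net = random_graph("er", seed=11, n=100, p=0.04)
state = asynchronous_coreness(net, seed=0, schedule="uniform")
print(f"initial convergence: {state.updates} single-node updates "
      f"on {net.n_nodes} nodes / {net.n_edges} edges")
print(f"matches pruning oracle: {state.g == coreness_by_pruning(net).coreness}")

new_edges = [("1", "2"), ("3", "50"), ("7", "90")]
old = dict(state.g)
resumed = resume_after_edge_addition(net, state.g, new_edges, seed=1)
changed = sum(1 for n in old if resumed.g[n] != old[n])
print(f"after inserting {len(new_edges)} edges: only {changed} of {net.n_nodes} "
      f"converged values changed; the rest were reused as-is")
print(f"still matches a fresh oracle: {resumed.g == coreness_by_pruning(net).coreness}")
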