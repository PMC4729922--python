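"""Scoring centralities against simulated spreading influence.

Simulates SIR outbreaks seeded at every node of a 300-node random graph at
1.5 times the mean-field epidemic threshold, then reports the tie-aware
Kendall tau between each centrality and the per-node mean outbreak size.
Higher tau = the centrality better predicts who the influential spreaders
are.
"""

from hcore import (
    SpreadingConfig,
    betweenness,
    closeness,
    correlation_report,
    epidemic_threshold_hmf,
    random_graph,
    sir_influence,
    synchronous_h_family,
)

net = random_graph("er", seed=5, n=300, p=8 / 299)
beta_c = epidemic_threshold_hmf(net)
cfg = SpreadingConfig(beta=1.5 * beta_c, runs=200, rng_seed=1)
print(f"beta_c (mean-field) = {beta_c:.4f}; simulating at beta = {cfg.beta:.4f}, "
      f"{cfg.runs} outbreaks per node ...")
influence = sir_influence(net, cfg)

table = synchronous_h_family(net)
report = correlation_report(net, influence, {
    "": table,  # expands to h(0)=degree, h(1)=H-index, ..., h(n_inf)=coreness
    "closeness": closeness(net),
    "betweenness": betweenness(net),
})
print(report[["centrality", "tau", "best"]].to_string(index=False))
print("h(0) is degree, h(1) the classical H-index, the last order coreness;")
print("the flagged row is the best influence predictor for this network.")
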