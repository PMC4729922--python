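# Methods

## The operator and the family

For a finite multiset of reals, H(x₁,…,xₙ) is the largest integer y such
that at least y of the xᵢ are ≥ y (H of the empty multiset is 0, so an
isolated node carries 0 at every order).  The family starts at
h⁽⁰⁾ᵢ = kᵢ (degree) and iterates h⁽ⁿ⁾ᵢ = H over the neighbours'
h⁽ⁿ⁻¹⁾ values, all nodes updated from the same snapshot.  Two facts drive
everything: the per-node sequence is monotonically nonincreasing (H over a
node's neighbours never exceeds the neighbour count, and H is monotone in
its arguments), and the limit equals the k-core shell index cᵢ.  The test
suite asserts both on a corpus of 250 seeded random graphs against an
independent bucket-queue peeling, plus the auxiliary inequalities used in
the convergence argument (induced-subgraph domination and the
minimum-degree lower bound).

The convergence time n∞ is detected operationally: iterate until the first
sweep that changes no value; n∞ is the number of changing sweeps (0 when
the degrees are already the fixed point, as on any regular graph).  No
separately computed coreness enters this detection; the oracle-equivalence
tests enforce agreement instead.

## Asynchronous updating

Every node starts at its degree; one node at a time recomputes its value
from its neighbours' *current* values.  Convergence to coreness holds for
any schedule that updates every node often enough, because values decrease
monotonically from above and remain bounded below by coreness.  Built-in
schedules: `uniform` (seeded random choice), `round_robin`, and
`stalest_first` (always the longest-unupdated node, an adversarially
regular order); custom callables are accepted, since smarter schedules
(e.g. demoting nodes whose values rarely change) are an open design space.
Termination is detected exactly, not probabilistically: after every |V|
scheduled updates a deterministic verification pass applies the operator
at every node and stops when nothing would change — the literal
steady-state condition.

### Growing networks

Resuming after edge insertions is where the decentralized form pays off,
but the obvious rule — reset only the new edge's endpoints to their new
degree — is unsound.  Inserting an edge between two leaves of a star
raises the *centre's* coreness from 1 to 2 while the centre still holds
g = 1; since the process only converges from above, it can then lock in
at values below the new coreness (we observed exactly this, update-order
dependent).  The implementation instead uses the locality result from
incremental k-core maintenance: an inserted edge (u, v) can raise coreness
only for nodes in shell k = min(cᵤ, cᵥ) reachable from the endpoints
through shells ≤ k, and only by 1.  `resume_after_edge_addition` bumps
that region to k+1, resets the endpoints to their new degree, and
reconverges — per edge, so each region is computed from exact coreness
values.  Everything outside the region keeps its converged value
untouched.  The suite validates 20 successive random insertions against a
fresh pruning oracle after every one.

## Pruning decompositions

`coreness_by_pruning` is the standard O(|E|) bucket-queue peeling (process
nodes in nondecreasing current degree; the shell index only ever grows).
Isolated nodes get coreness 0, consistently with the operator convention.
Directed variants peel by in- or out-degree, with removals cascading along
the opposite direction.

**Weighted convention.**  The weighted family could not simply seed the
plain operator with strengths: H over neighbour strengths is not bounded
by a node's own strength (two nodes joined by a weight-5 edge would
converge to 1 while any strength-based shell notion says 5), so the
monotone-from-above argument collapses.  We instead define a weighted
operator — the largest integer y such that the total *edge weight* to
neighbours with value ≥ y is at least y — seeded with node strength.  With
unit weights this reduces exactly to the plain operator, the sequence is
again nonincreasing, and its fixed point matches the integer
strength-threshold peeling (`weighted_coreness_by_pruning`: node i gets
the largest integer s such that it survives iterative removal of nodes
with remaining strength < s).  This pairing is this package's convention;
tests validate the fixed-point identity on random integer-weighted graphs.

## Spreading models

**SIR** (default λ = 1): synchronous generations; every infected node
contacts each susceptible neighbour independently with probability β,
then the previously infected nodes are removed with probability λ.  With
λ = 1 each node is infectious for exactly one generation (the
independent-cascade limit) and a dedicated frontier-based fast path is
used.  Influence Rᵢ is the mean final removed count over `runs` outbreaks
seeded solely at i; one RNG stream is derived per (master seed, node, run)
so results are independent of evaluation order and bit-reproducible.

**Thresholds.**  The mean-field estimate βc = ⟨k⟩/(⟨k²⟩−⟨k⟩) from the
empirical degree moments is the default operating point, with spreading
rates quoted as multipliers (1.5/2/2.5 × βc) — small enough that outbreak
size still depends on the seed.  A simulation-based estimator is also
provided: scan a β grid, start outbreaks from uniformly random seeds, and
take the β maximizing the susceptibility (variance/mean) of final outbreak
size.  It agrees with the mean-field value within a factor of two on the
tested sparse random graphs.

**SIS**: parallel discrete-time updates (infection probability
1−(1−β)^m with m infected neighbours; recovery with λ), all-infected
initialization, a discarded transient (default 100 steps), then Rᵢ =
fraction of sampled steps node i is infected, averaged over realizations.
Realizations that hit the absorbing all-susceptible state are restarted up
to `max_restarts` times; below threshold (always at β = 0) restarts are
exhausted, the realization counts as zero, and the output metadata flags
how many died out.  These protocol details (initialization, transient,
restart policy) are this package's choices, surfaced as parameters.

**Bond percolation**: each run keeps every edge independently with
probability p; influence is either giant-component membership frequency
(size ties broken deterministically by smallest component label) or mean
component size.  By analogy with the SIR convention, p defaults to a
multiplier of βc in the CLI.

## Evaluation

The Kendall tau follows the tie-dropping definition: over all N(N−1)/2
unordered pairs, a pair is concordant/discordant only if strictly ordered
in both coordinates; tied pairs count toward neither but stay in the
denominator.  This is *not* tau-b — with heavily tied integer indices
(coreness above all) it is systematically smaller in magnitude, and a
vector scored against itself gives < 1 when ties exist.  The O(N log N)
implementation (sort by (x, y) + merge-sort inversion counting with
tie-group inclusion–exclusion) returns exact integer pair counts and is
tested for equality against the O(N²) scan on 10⁴ random sequences.

Closeness is 1/Σⱼ d(i, j) over nodes reachable from i (disconnected
networks trigger a warning since cross-component values are not
comparable); betweenness is the unnormalized geodesic-share sum over
unordered pairs (networkx's Brandes implementation behind the module
surface — ordered summation would merely double every value and leave all
rankings unchanged).

## Synthetic data

The generators produce all test inputs, so nothing needs downloading:
canonical closed-form fixtures (stars, cliques, paths, cycles), seeded
Erdős–Rényi graphs, a pinned preferential-attachment construction
(initial K_m clique, m degree-proportional targets per arrival, sampled
without replacement — edge count C(m,2) + (n−m)m, reproducible by seed),
and the hierarchical star-of-stars tree with per-node level attributes
(level 1 = root; level ℓ ≥ 2 holds L^(ℓ−1) nodes).  The random corpus
used in the fixed-point tests is 200 ER(n=100, p=0.05) plus 50
preferential-attachment (n=200, m=3) graphs; the end-to-end influence
evaluation uses a 500-node graph with 200 outbreaks per node — desk-scale
sizes chosen so the whole suite re-runs in minutes while the corpus still
spans sparse/dense, homogeneous/heavy-tailed regimes.  What synthetic
graphs do not emulate: the clustering, assortativity and community
structure of real networks, which shift the *values* of influence
correlations (and convergence times) even though the exact fixed-point
identities tested here hold on any finite simple graph.  Published
convergence times for the eight standard benchmark networks are encoded in
the test catalog and verified automatically for any edge list supplied
under `data/real/`.

## Numerical and degenerate-input choices

- Resolution rate (probability two distinct nodes differ in an index) uses
  unordered distinct pairs.  It is *not* monotone along the family on
  small random graphs — only the qualitative endpoints (degree resolves
  best; coreness worse than degree) are stable, and the tests assert only
  that.
- Information coverage counts the ball of radius n including the node
  itself, as a fraction of |V| — taken as stated even though h⁽ⁿ⁾ formally
  aggregates topology up to distance n+1's degrees; it is a diagnostic,
  not an input to any computation.
- Edge lists: whitespace-separated, `#` comments, optional positive third
  weight column; self-loops and duplicate (including reciprocal) edges are
  dropped with warnings rather than rejected, since declared-simple public
  datasets frequently are not.
- Clustering in the network summary averages local coefficients over nodes
  of degree ≥ 2 only; assortativity is the degree–degree Pearson
  coefficient over edge endpoint pairs; mean distance averages over
  reachable ordered pairs (no infinities from disconnected components).
- Degenerate guards: empty networks raise; all-degree-≤1 networks report
  clustering 0 with a warning and have no defined epidemic threshold
  (⟨k²⟩ ≤ ⟨k⟩ raises).

## Known limitations

- The asynchronous updater models decentralization within one process;
  there is no actual message passing or multi-process deployment.
- Incremental recomputation covers edge/node additions only — deletions
  can lower coreness and would need a different repair rule.
- The SIS and percolation protocol parameters are conventions (documented
  above), so their absolute R values are comparable only within this
  package; rankings are the intended use.
- `epidemic_threshold_simulated` is a coarse grid estimator; it locates
  the susceptibility peak only up to the grid resolution.
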