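# Methods

## Model

Agents occupy the sites of an `L × L` square lattice without periodic
boundaries. Agent `i`'s culture is a vector `(f_1,i, …, f_F,i)` of `F`
traits, each an integer in `{0, …, q−1}` drawn i.i.d. uniformly at
initialisation. Traits are stored 0-based; any 1-based presentation is an
I/O concern only.

One elementary event — one time step, whether or not anything changes —
consists of: draw `i` uniformly from the `N = L²` agents; draw `j` uniformly
from `i`'s lattice neighbours; decide interaction; on interaction, possibly
copy one trait from `j` to `i`. At most one matrix entry changes per event,
and traits can never leave `{0, …, q−1}` (copying creates no new values).

**Standard rule.** Interaction probability = (number of features on which
`i` and `j` agree) / `F`; the copied feature is drawn uniformly from the
disagreeing ones. A copy between a pair can only raise that pair's future
interaction probability.

**Agreement-threshold rule.** Traits are treated as ordered. With threshold
`a ∈ {0, …, q−1}`, the interaction probability is the fraction of features
with `|f_k,i − f_k,j| ≤ a`. Features at distance zero count toward this
probability: the rule then mirrors the standard rule's counting of common
features and guarantees the threshold-mode probability is never below the
standard one, which is the stated intent of the mechanism. Only disagreeing
features within the threshold can be copied, so a copy leaves the pair's own
interaction probability unchanged (distance `d ≤ a` becomes distance 0, both
inside the threshold count).

Candidate selection in threshold mode is genuinely ambiguous between two
readings, and both are implemented behind `selection_rule`:

- `within_threshold` (default): the candidate feature is drawn among
  disagreeing features already within the threshold — no wasted draws;
- `literal_two_stage`: the candidate is drawn among *all* disagreeing
  features and the copy is then rejected if `|Δ| > a` — a literal
  choose-then-check double application of the threshold.

The two rules have identical absorbing states (an edge admits a change under
one iff under the other); only transient kinetics differ. Unit tests cover
both; ensembles default to `within_threshold`.

## Absorbing states

A state is absorbing when no lattice edge can ever produce a change: in
standard mode every neighbouring pair shares 0 or all `F` features; in
threshold mode no neighbouring pair has a feature at distance `d` with
`0 < d ≤ a`. The run loop performs this exhaustive `O(edges × F)` scan every
`N·F` events (configurable), including once before the first event — so the
frozen `a = 0` limit absorbs immediately with its initial matrix intact —
and stops at a `max_steps` cap (default 10⁷ events) otherwise, returning
`absorbed=False` with a logged warning rather than an error. Capped runs are
kept in ensemble tables and flagged; dropping them would bias means.

Two limits are load-bearing checks rather than empirical claims: `a = q − 1`
makes every interaction able to copy, so the connected lattice always ends
in a single cluster; `a = 0` forbids every copy, so the final state equals
the initial one exactly.

## Clusters

The headline statistic is the **non-spatial** cluster count: opinion-based
groups are equivalence classes of identical culture vectors over all `N`
agents, with singletons (isolates) counted as clusters of size 1 so sizes
always sum to `N`. Classic spatial cultural regions (lattice-connected
components of identical culture) are reported only as a comparison; they can
never be fewer than the non-spatial clusters. `relaxed_components(state, m)`
groups agents connected by chains of pairs agreeing on at least `F − m`
features; `m = 0` reduces exactly to the strict count and the count is
non-increasing in `m`. Because the cluster-size statistic of interest is not
uniquely pinned down, per-run tables carry both the largest and the mean
cluster size.

## Graph views

The bipartite graph has agent nodes and (feature, trait) attitude nodes;
each agent has degree exactly `F`. Unheld attitude combinations are omitted
by default (an `all_nodes` option includes all `F·q` for stable layouts
across states). Projections use networkx's weighted bipartite projection:
attitude-projection weights count agents co-holding both endpoints (two
traits of one feature are never linked), agent-projection weights count
shared features. Edge-weight terciles for display are rank-based
(sort-and-split) with boundary ties assigned to the lower bin, making the
labelling deterministic and order-independent; display classes for agent
projections (all `F` / `F−1` / fewer shared) are parameterised by `F`.
Exports (GraphML, weighted edge list) always contain all nodes; the
giant-component restriction exists only as a plotting option.

Lattice-view edge styling generalises the classic four classes to any `F`:
shared `= F` → no line, `> F/2` → dotted, `(0, F/2]` → dashed, `= 0` → thick
solid (frozen boundary). This is a deliberate design choice: fixed
shared-count class boundaries do not transfer across `F`.

## Ensembles and seeding

A sweep covers the grid `(L, q, F, a)` in lexicographic order with `n_runs`
realisations per cell (default 1,000; `--fast` uses 100). Seed derivation:
`SeedSequence(master_seed, spawn_key=(cell_index, run_index))`, truncated to
31 bits and recorded per row, so any row reproduces independently and
parallel execution (`n_jobs`) is bit-identical to sequential. Each run uses
one `numpy` Generator for initialisation; the compiled event loop (numba)
seeds its own Mersenne Twister from a value drawn off that Generator. The
pure-Python event loop (`engine="python"`) shares the exact event semantics
— property tests compare the two against the same absorbing-state oracle —
but consumes a different RNG stream, so trajectories agree between engines
only in distribution, not event-by-event. Cluster-count densities are exact
discrete frequencies (the count is an integer); no kernel smoothing outside
plots.

## Problem sizes used in the checks

The test suite and the acceptance script run scaled-down versions of the
full campaigns — 200 runs per cell at `N = 100` for the mean-clusters trend
over `(F, a)` at `q = 5`, 100 runs for the `F = 6, q = 3, a = 1`
multi-group fraction, 50 seeded runs for the consensus limit — sizes chosen
so the whole suite completes in well under a minute of simulation while the
trend gaps still clear two standard errors comfortably. Oracle checks
(exhaustive event enumeration, brute-force row deduplication, pairwise
projection counting) run at small `L` where `O(N²F)` is trivial.

## What the generator does and does not emulate

Initial states are i.i.d. uniform categorical matrices: the theoretical
setting of the model, not empirical survey marginals. Real Likert data have
non-uniform, correlated item distributions; passing tests therefore validate
the mechanism and its limits, not any claim about a particular survey
population. Seeding the model with empirical response matrices is supported
only passively (a state CSV can be loaded for the statistics and plotting
modules) and is otherwise out of scope, as are non-lattice topologies,
per-feature `q`, noise/media variants and trait averaging.

## Numerical and degenerate-input notes

- All draws (agent, neighbour, feature) are RNG-based; no index-order bias.
- An interaction whose eligible feature set is empty (e.g. an identical pair
  in standard mode, where the probability is 1) is a null event, not an
  error; the step counter always advances.
- `is_pair_active` operationalises "no future event can change the state";
  in threshold mode a nonempty `{k : 0 < |Δ_k| ≤ a}` already implies a
  positive interaction probability.
- Tercile binning of a constant weight set degenerates to a single lowest
  bin with equal boundaries.
- SVG output fixes matplotlib's hash salt and drops the timestamp, so
  repeated plot invocations are byte-identical; spring layouts require an
  explicit seed.
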