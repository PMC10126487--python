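# Methods

## Scope and model philosophy

`crossfeednet` analyses facilitative interaction networks inferred from
microbial community time series. The dependency-inference core is a
**set-based cross-feeding model**: each species is described by a set of
required metabolites (all needed for growth) and a set of secreted
metabolites (emitted when, and only when, growing). This is a deliberate
simplification of constraint-based community modeling — no stoichiometry,
no fluxes, no biomass objective — chosen so that every downstream quantity
(coupling scores, minimal media, transfer tables) is *exactly enumerable*
and can be verified by brute force at desk scale. Outputs should be read
as a boolean "who can feed whom" analysis, not as quantitative flux
predictions.

## Community growth closure

Given a member set and a medium, growth is the least fixed point of:
start with the medium available and nobody growing; repeatedly mark any
member whose requirements are all available as growing and pool its
secretions; stop at stability. The update is monotone, so the fixed point
is unique and order-independent, and enlarging the member set or medium
can never shrink the growing set. A consequence worth noting: a mutual
dependency pair with no external producer of its loop metabolites can
never bootstrap — feedback loops in feasible communities always hang off
an external entry point.

## Species coupling score (SCS)

SCS(recipient ← donor) is defined over sub-communities S that contain
both species and in which the recipient grows: the fraction of such S in
which the recipient fails to grow in S∖{donor}. Conditioning on
recipient growth is this package's fixed convention (documented here
because several published variants exist); an empty conditioning set
yields 0 with a warning. Enumeration is exhaustive over all 2^(n−2)
sub-communities for communities of ≤ 12 species (`exhaustive_limit`);
larger communities use uniform Monte-Carlo sampling (each other species
present with probability 1/2) with an explicit seed. The matrix routine
memoizes growth closures by member set, so the exhaustive matrix costs
roughly one closure per distinct subset rather than per (pair, subset).

Replicate runs (default 10, seeded `base_seed + i`) exist to quantify
sampling variability. In exhaustive mode the result is provably
seed-independent, so the matrix is computed once and replicated across
run records; the reported SD is exactly zero. Monte-Carlo means converge
to the exhaustive values (checked to within three standard errors at
10^4 samples in the test suite).

## Transfer attribution, MIP and MRO

For growing donor b, growing recipient a, and metabolite m secreted by b,
required by a, and absent from the medium, one (b, a, m) record is
emitted. A metabolite's frequency is the number of distinct (donor,
recipient) pairs transferring it; standardized frequencies divide by the
per-time-point total so each day sums to 1.

**Metabolic interaction potential** MIP = |⋃ requirements| − (minimal
medium size under exchange). Without exchange each species needs its full
requirement set externally, so the non-interacting minimal medium is the
requirement union. Any required metabolite that nobody secretes must be
in every feasible medium ("forced"); the exact search therefore only
branches over producible candidates, by increasing subset size, and is
used when those number ≤ 20 (`exact_limit`). Beyond that a greedy
elimination yields a minimal-by-inclusion medium — an upper bound on the
minimum, hence a *lower bound* on MIP — and the result is flagged
inexact. Any community grows on its own requirement union, so MIP is
always defined.

**Metabolic resource overlap** MRO = mean over unordered species pairs of
|Req_a ∩ Req_b| / min(|Req_a|, |Req_b|); pairs with an empty denominator
are skipped. The denominator is configurable (`min` default, `union`,
`mean`) and recorded in output metadata.

## Turnover statistics

Columns are normalized to relative abundances **before** window
averaging (depth varies by day; the alternative order is not exposed
because averaging raw counts would weight days by sequencing depth). The
abruptness at 1-based time point t with window w is the Bray-Curtis
dissimilarity between the mean compositions of the inclusive windows
[t−w+1, t] and [t+1, t+w]; it is defined where both windows fit. On
normalized windows BC equals half the L1 distance, so a value > 0.5
means the windows share less than half their composition. Gapped
sampling schedules are handled by building windows over consecutive
*samples*; a `require_contiguous_days` flag restricts reporting to
calendar-contiguous windows instead.

## Networks

Edges point donor → recipient (direction of metabolite flow). An edge is
kept when the mean SCS across runs is strictly greater than the threshold
τ (default 0: any positive mean dependency draws an edge; no published
cutoff exists, so τ is an explicit config value) and both endpoints are
detected at the time point. Detection is abundance ≥ θ and strictly
positive (θ default 0, i.e. presence). Loop edges are those whose
endpoints share a strongly connected component of size ≥ 2, plus
self-loops. Edge-list TSVs carry the node list in a header comment so
isolated nodes — which enter orderability and centrality denominators —
survive a round trip; GraphML export is also available.

## Hierarchy metrics

All three indices operate on the condensation (SCC quotient) with node
weights α(v) = SCC size. Self-loops make a singleton SCC cyclic but are
dropped from the condensation DAG.

- **Orderability** O = (nodes in acyclic singleton SCCs) / (all nodes).
- **Feedforwardness** F = mean over all maximal-to-minimal condensation
  paths π of |π| / Σ_{v∈π} α(v), where |π| counts nodes. A node that is
  both maximal and minimal contributes the one-node path through itself
  (so an n-node cycle condensing to a point gives F = 1/n). Path
  enumeration aborts with an explicit error beyond `max_paths` (10^5)
  rather than silently sampling.
- **Treeness** T averages f(g) = (H_f − H_b)/max(H_f, H_b) (0 when both
  entropies vanish) over a leaf-removal sequence of the condensation.
  H_f is the mean, over maximal nodes, of the entropy of the
  uniform-branching path distribution, computed by the linear recursion
  h(v) = log₂ k_out(v) + mean of h over successors (h = 0 at sinks); H_b
  is the same on the reversed DAG. Entropies are in bits; the f ratio is
  base-independent.

**Pruning convention.** Each pruning step removes *both* the maximal
(in-degree 0) and minimal (out-degree 0) nodes of the current graph, and
the sequence stops when the graph is empty or edgeless. Removing both
extremes makes the pruning schedule commute with edge reversal, so the
antisymmetry T(G reversed) = −T(G) holds exactly — removing only minimal
nodes breaks it (a five-node counterexample: edges a→b, a→c, b→d, c→d,
e→d). Canonical values are unaffected: out-star +1, in-star −1, chain 0.

## Centrality

Influence is unweighted local reaching centrality,
I(v) = |{u ≠ v reachable from v}| / (N−1). It ignores edge weights — a
documented limitation — and is pluggable (`influence_strategy`) should an
attenuated or weighted variant be preferred. PageRank uses damping
d = 0.85, uniform teleport, uniform dangling-node redistribution, and
power iteration to an L1 tolerance of 1e-10 (error with diagnostics on
non-convergence); edge weights are optionally used as transition
probabilities but are off by default so both rankings answer the same
unweighted question. Keystone tables aggregate per-run, per-day scores
into mean/SD summaries and top-k rankings.

## Synthetic study systems

The time-series generator emulates the qualitative shape of a long
co-culture experiment: default 32 species observed daily for 110 days; a
deterministic geometric rank-abundance skeleton; an instantaneous shift
at day 18 (the shift is modeled as a single-column event because the
emulated transition is rapid; a gradual ramp is out of scope) moving 90%
of total abundance to a disjoint 4-species quasi-stable set; optional
linear recovery returning half the displaced mass by the end of the
series; i.i.d. multiplicative log-normal noise (σ = 0.3) per entry.
Magnitude, richness and noise defaults are free parameters chosen to
produce a clearly detectable shift with realistic day-to-day wobble; the
emulated experiment did not quantify them. The generator does **not**
model mechanistic population dynamics, compositional correlations, or
sequencing noise, so passing tests show the *statistics* behave correctly
on planted structure, not that real communities satisfy the model.

The community generator lays out a metabolite universe (medium +
one byproduct per species + two dedicated metabolites per planted loop),
an index-ordered backbone in which each species' extra requirement is
cross-fed from a lower-index provider with probability
`crossfeed_density`, and planted 2-species dependency loops. Loop members
require each other's loop metabolite; because an unseeded mutual
dependency can never bootstrap, one or two non-loop "helper" species also
secrete the loop metabolites (two helpers when space permits, which makes
the loop visible in the SCS network as well as in the designed dependency
digraph). By construction every species grows in the full community and
the designed dependency digraph contains exactly `loop_count` directed
cycles. Both generators draw all randomness from one seeded
`numpy.random.Generator` per call.

## Pipeline and problem sizes

The `run-all` pipeline simulates (or loads) inputs, computes abruptness,
runs replicate coupling analyses, and emits per-day networks, hierarchy
reports, per-run centralities with mean/SD, transfer tables (raw and
standardized), MIP/MRO per detected sub-community, and a manifest with a
configuration hash and all seeds; reruns with the same configuration are
bit-identical. The default per-day schedule is 13 time points (days 1,
10, 20, 24, 30, 40, …, 110), mirroring a typical sparse metagenome
sampling design. Default synthetic community size is 12 species — the
largest size at which coupling scores are exhaustively enumerated rather
than sampled — which keeps a full pipeline run to a couple of seconds.
Test-suite property checks use exhaustive graph enumeration at 3 nodes
(512 digraphs incl. self-loops) plus seeded random samples at 4–5 nodes;
exhaustive 5-node enumeration (2^20 graphs) adds no generality for these
oracle-equivalence checks and is not worth its cost. Days with fewer than
two detected species skip hierarchy/centrality with a structured
"insufficient nodes" record rather than failing.

## Known limitations

- Boolean growth has no notion of partial limitation or uptake
  competition; SCS = 0 can coexist with quantitatively important flows.
- Secretion is unconditional on anything except growth; no secretion
  costs or regulation.
- Influence centrality ignores edge weights and path lengths.
- Monte-Carlo SCS is a ratio estimator (consistent; bias O(1/n)).
- The greedy MIP fallback reports only a lower bound.
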