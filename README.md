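# crossfeednet

Facilitative (cross-feeding) interaction networks from microbial community
time series.

Microbial communities can collapse abruptly, and one proposed mechanism is
the presence of **positive feedback loops** in the web of metabolic
dependencies: when species feed each other, the decline of one member can
cascade through the loop. `crossfeednet` is a toolkit for ecologists and
systems biologists who want to ask, from a species-by-time abundance table
and per-species metabolic descriptions:

- *When* did the community shift, and how fast? (windowed Bray-Curtis
  **abruptness** index)
- *Who depends on whom*, and through which metabolites? (directional
  **species coupling scores** from a set-based cross-feeding model, with
  metabolite-transfer attribution and community-scale **MIP**/**MRO**
  facilitation/competition indices)
- *How hierarchical is the dependency network*, and does it contain
  feedback loops? (**treeness**, **feedforwardness**, **orderability** on
  the SCC condensation)
- *Which taxa are keystones*? (**influence** / reaching centrality and
  **PageRank** rankings)

A synthetic-data module generates abundance series with planted abrupt
shifts and toy communities with planted dependency loops, so the whole
pipeline is testable without any sequencing data.

## The statistics in brief

**Abruptness.** For window width *w* (default 5 days) and time point *t*,
columns are normalized to relative abundances, averaged over the windows
[*t*−*w*+1, *t*] and [*t*+1, *t*+*w*], and compared by Bray-Curtis
dissimilarity BC(u, v) = Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ). A value above 0.5 means
more than half of the community composition turned over.

**Species coupling score (SCS).** In the set-based model a species grows
once all its required metabolites are available (medium plus the
secretions of already-growing members; least fixed point). The SCS of a
recipient on a donor is the fraction of sub-communities (containing both,
and in which the recipient grows) where deleting the donor abolishes the
recipient's growth: 0 = independence, 1 = essentiality. Sub-communities
are enumerated exhaustively up to 12 species, sampled uniformly beyond.

**Hierarchy metrics.** On the node-weighted condensation (SCC quotient)
of the directed network: *orderability* O is the fraction of nodes outside
any feedback loop; *feedforwardness* F is the mean over
maximal-to-minimal condensation paths of path length divided by the summed
SCC sizes along the path (1 on DAGs); *treeness* T contrasts forward and
backward path entropies, f = (H_f − H_b)/max(H_f, H_b), averaged over a
leaf-removal sequence (+1 pyramidal, −1 inverted, 0 symmetric).

**Centrality.** Influence I(v) = |nodes reachable from v| / (N−1);
PageRank with damping 0.85, uniform teleport and dangling redistribution.

## Worked example

```python
from crossfeednet import *

# a 32-species, 110-day series with a planted shift at day 18
series = simulate_timeseries(TimeSeriesSpec(seed=1))
a = abruptness(series, w=5)
print("peak day:", a.argmax_day, "abruptness:", round(float(a.a.max()), 3))

# a 10-species toy community with 2 planted dependency loops
model = simulate_exchange_community(
    ExchangeSpec(n_species=10, crossfeed_density=0.7, loop_count=2, seed=1))
rep = replicate_runs(model, n_runs=10, base_seed=1)
print("MIP:", rep.scores.mip, " MRO:", round(rep.scores.mro_mean, 3))

net = build_network(rep.runs, day=20)
h = hierarchy_report(net)
print(f"T={h.T:.3f}  F={h.F:.3f}  O={h.O:.3f}")
c = centrality_report(net)
top = c.ranking("influence")[:3]
print("top influence:", [(v, round(c.influence[v], 2)) for v in top])
```

prints

```
peak day: 17 abruptness: 0.908
MIP: 6  MRO: 0.156
T=0.000  F=0.774  O=0.600
top influence: [('sp01', 0.56), ('sp03', 0.44), ('sp02', 0.22)]
```

The abruptness series peaks at day 17 — the last day of the trailing
window before the planted day-18 shift — at 0.91, i.e. ~91% compositional
turnover between the two 5-day windows. The community can dispense with 6
external metabolites thanks to exchange (MIP = 6) while mean pairwise
requirement overlap (potential competition) is 0.16. The inferred network
has orderability 0.6: 40% of detected species sit inside feedback loops.
Species sp01 can reach 56% of the other species along directed dependency
edges, making it the top keystone candidate by influence.

The same analyses are available as a CLI (`crossfeednet simulate-ts`,
`abruptness`, `exchange`, `network`, `hierarchy`, `centrality`, and
`run-all` for the full pipeline with a manifest and per-day outputs).

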