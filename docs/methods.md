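# Methods

## Model and assumptions

All proximity scores are functions of unweighted shortest-path lengths
(hop counts) on an undirected protein–protein interactome. The package
never weights interactome edges by confidence or degree; the proximity
literature offers degree-preserving nulls and separation measures, but the
scoring model implemented here deliberately uses uniform random-pair nulls
and the four distance statistics listed in the README. Key structural
assumptions:

- **Finite distances.** Every metric term assumes a path exists. By
  default the interactome loader restricts to the largest connected
  component (`restrict_lcc=True`; ties between equal components go to the
  one containing the lexicographically smallest node). If LCC restriction
  is disabled, an unreachable pair raises an error — infinite distances
  are never silently substituted, because a single ∞ would poison every
  averaged score.
- **Target sets are unweighted.** An entity's targets enter as a set;
  predicted and experimental annotations, if a user's catalog mixes them,
  are treated identically. Targets absent from the interactome are
  dropped with a logged count; an entity whose *every* target is off-graph
  raises, since its proximity is undefined.
- **Directionality.** Closest and shortest distances are symmetric;
  disease proximity is directed (averaged over *disease genes*, each to
  its nearest drug target). `d(X,Y)=0` iff the disease genes are a subset
  of the drug targets — the asymmetry matters and is covered by tests.

### Normalization of the shortest distance

The average-over-all-pairs statistic `d^S` is normalized by `|a|·|b|`, the
number of summed terms, so it is a true mean — this is the default
(`shortest_norm="product"`). A `"sum"` switch dividing the same numerator
by `|a|+|b|` is exposed for compatibility with conventions that normalize
by total set size; it rescales but does not reorder pairs with equal set
sizes.

### Significance regimes

1. **Random-pair Fisher Z** (ingredient–ingredient and herb–herb scoring
   inside formulas): the null is `n=1000` pairs drawn uniformly *with
   replacement* from the relevant pair universe, seeded.
   `Z = (x − μ_null)/σ_null` with `σ_null` the sample standard deviation
   (ddof=1). The p-value is the standard-normal **lower** tail Φ(Z):
   proximity is evidence of interaction when the distance is *small*, so
   the rejection region is the left tail. Significant ⇔ p < 0.05, raw —
   no multiple-testing correction by default (a Benjamini–Hochberg helper
   is available for users who screen large families).
2. **Per-test disease nulls** (repositioning): each screen samples one
   1000-pair null from its (entity, disease) universe, shared across the
   screen's rows. A per-row null would cost n_entities × 1000 distance
   evaluations for no change in ordering; a per-screen null keeps screens
   linear and the Z-scores comparable within a screen.
3. **Empirical 5% tail** (browse scale): the null is the exhaustive pool
   of pairs co-occurring in at least one formula (deduplicated across
   formulas, no sampling, no seed); the threshold is the nearest-rank
   q-quantile (rank ⌈q·n⌉, 1-based ascending, q=0.05), and a pair is
   flagged when its distance ≤ threshold. By construction the flagged
   fraction of the pool itself is ⌈q·n⌉/n.

A known property of regimes 1–2: the null universe includes the truly
interacting pairs, so strong signal *contaminates* the null, pulling
μ_null down and inflating σ_null. Calibration stays near 5% on
null-dominated universes (verified in the acceptance suite), but power
drops when a large fraction of the universe is signal — see "Sensitivity"
below.

## Landscapes, communities, ADMET

Recommendation queries assemble a typed landscape (ingredient/herb/disease
nodes; edges carry distance, Z, p). For module analysis the landscape
becomes a weighted graph with `w = exp(−d)`: monotone decreasing and
finite at d = 0, where shared-target pairs sit (a 1/d transform would be
singular exactly at the most interesting edges). By default only
significant (p < 0.05) edges enter the graph. Community detection is
Louvain modularity maximization (networkx implementation), seeded, with
nodes processed in deterministic order and community labels renumbered by
smallest member; resolution defaults to 1.0 and is exposed. The *disease
module* is the community containing the disease node, minus the disease
node itself.

ADMET filtering is pure consumption of a property table (categorical
`+`/`−` or numeric columns): a conjunctive spec of
`(property, eq|ge|le, value)` terms; candidates missing a referenced
property are excluded and logged, never passed by default. Filtering is
antitone in the spec — adding a conjunct can only shrink the surviving
set — which the tests assert.

## Synthetic scenarios

`generate_scenario` emulates the *shape* of a curated catalog, not its
content. Defaults, chosen once as a desk-scale study condition:

| parameter | default | rationale |
|---|---|---|
| interactome | Barabási–Albert, n=1000, m=3 | heavy-tailed degree like real PPI networks; ~3000 edges, diameter ≈ 6 |
| disease module | 30 genes | BFS ball around a random centre: connected by construction |
| ingredients | 20 planted + 80 background | 20% prevalence gives both signal and a null-dominated pair universe |
| targets per ingredient | 8 | typical small-molecule polypharmacology scale |
| proximity bias | 0.8 | planted ingredients draw ⌈0.8·8⌉ targets inside the module, rest uniform |
| grouping | 4 ingredients/herb, 5 herbs/formula | puts all planted ingredients in one formula; consecutive planted ingredients form the 10 planted pairs |

At bias 0 planted and background draw from the same distribution
(exchangeable; verified by rank-sum uniformity over seeds); at bias 1 a
planted ingredient's targets lie wholly inside the module, forcing many
zero terms in its disease proximity. The planted/background mean distance
gap is monotone in the bias (acceptance suite, 10 seeds).

What the generator does **not** emulate: realistic interactome topology
beyond the degree distribution, correlated target annotations between
chemically similar ingredients, incomplete/noisy disease-gene sets, or
herb-frequency skew. Passing tests therefore demonstrate correctness of
the inference machinery and recoverability of planted signal under clean
conditions — not expected performance on curated biological catalogs.

## Numerical choices

- Distances are computed by per-set multi-source BFS, cached by frozen
  target set; a screen over k entities costs O(k·(V+E)). Exactness
  against a naive all-pairs reference is asserted on 200 random graphs.
- Ties everywhere break lexicographically (LCC selection, center
  ingredients, ranks at equal distance), making all outputs independent
  of catalog row order.
- Serialized distances carry 6 decimals, p-values 4 significant digits;
  writers sort rows so identical seeds give byte-identical files.
- Degenerate nulls (σ_null = 0, e.g. a single-pair universe) raise rather
  than emitting infinite Z-scores.

## Problem sizes

The test and acceptance workloads use the default 1000-node scenario
(seconds per screen on one CPU); oracle-equivalence checks use 200 random
graphs of ≤ 40 nodes where exhaustive all-pairs enumeration is exact;
effect-size monotonicity uses 10 seeds × 4 bias levels. The exhaustive
modularity oracle for Louvain runs on an 8-node two-clique fixture (4140
partitions).

## Sensitivity and known limitations

- **Module recovery varies with the seed.** The disease module of the
  significant-edge landscape recovers 80% of planted ingredients at the
  default seed, but across seeds the recovery ranges widely (≈20–90%):
  when the per-test disease null happens to be strongly contaminated by
  planted signal, fewer ingredient–disease edges reach p < 0.05, the
  disease node's degree drops, and Louvain at resolution 1.0 may attach
  it to a fragment of the planted cluster. This is a property of the
  raw-p<0.05 + modularity pipeline itself, not of the implementation.
- The Fisher Z approximation assumes the null distance distribution is
  roughly normal; for very small target sets (1–2 targets) distances are
  coarsely discrete and the normal tail is only an approximation — the
  empirical-threshold regime is the robust alternative there.
- Louvain is a greedy heuristic: only on tiny fixtures is the partition
  certified against exhaustive modularity maximization.
- The prescription pattern scores cross-prescription pairs by default;
  within-prescription pairs are opt-in (`include_within=True`).
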