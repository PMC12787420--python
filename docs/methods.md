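# Methods

## Scope and data model

`netpharm` implements the inference chain of multi-herb network
pharmacology as pure file-in/file-out stages: compound-table curation,
target/disease-gene intersection, PPI centrality analysis with
iterative hub screening, gene-set over-representation, and D-H-C-T-P
network assembly. All inputs are plain text (TSV tables, one-per-line
gene lists, STRING-style edge lists, GMT libraries). Live database
retrieval (compound catalogues, disease-gene portals, interaction and
annotation servers) is out of scope by design; the synthetic module
generates statistically controlled stand-ins for every input.

## Curation rules

- Compound tables deduplicate on exact `(herb, PubChem CID)` pairs;
  the same CID under two herbs is two records, because shared
  constituents (e.g. glycyrrhizin) belong to both herbs' inventories
  and per-herb counts must add up.
- Compounds with no entry in the target map are excluded — the
  standard "no literature-annotated targets" rule.
- Gene symbols are normalised by trimming and upper-casing only. No
  alias or identifier mapping is attempted; this is a documented
  limitation, chosen because any alias policy would be both
  data-version-dependent and silently lossy.

## Centrality conventions

Degree is the raw integer neighbour count. Betweenness uses Brandes'
algorithm on unweighted shortest paths, normalised by `(n−1)(n−2)/2`;
node pairs in different components contribute zero. Closeness is
component-restricted, `(n_c − 1)/Σd`, with isolated nodes scored 0 and
no cross-component (Wasserman–Faust) rescaling. Edge confidence scores
are a pure inclusion filter (default cutoff 0.7, the conventional
"high confidence" level for STRING-style scores, configurable); they
never enter the path metric. This hop-count convention is what makes
degree values integers and closeness values exact small rationals on
hub-dominated graphs — in any graph with a universal node every
non-neighbour sits at distance exactly 2, so
`CC(v) = (n−1)/(DC(v) + 2(n−1−DC(v)))`.

Computation is delegated to networkx (`betweenness_centrality`
normalised, `closeness_centrality` with `wf_improved=False`); the test
suite checks both against independent brute-force oracles (BFS distance
sums; exhaustive shortest-path enumeration) on 100 random graphs with
n ≤ 8 at 1e−12 tolerance.

## Iterative mean-threshold screening

Each round takes the arithmetic mean of DC, BC and CC over the current
node set as three thresholds and retains the nodes *strictly* above all
three (conjunction; the strict rule follows the `DC > …` reading of
threshold-based hub screening, and guarantees strict shrinkage — no
node exceeds the mean of a constant vector). All three centralities
are recomputed on the induced subgraph every round; this recomputation
is what makes the second-round degree cutoff equal `2E/N` of the
*reduced* graph. Isolated nodes created by induction stay in the graph
(their closeness of 0 removes them at the next round) so no node is
dropped outside the audit trail.

Stopping policies: `convergence` (default) iterates until a round
retains nothing; that terminal round is recorded and the core is its
input node set. `rounds:k` and `size:m` stop early by round count or
core size. A round retaining every node would also stop the loop, but
cannot occur under strict thresholds; the guard exists for
configurability. Threshold comparisons always use full precision;
the 5-decimal (DC) / 6-decimal (BC, CC) rounding in
`thresholds_report` is display-only.

## Over-representation analysis

Fisher's one-sided test is computed as the exact hypergeometric upper
tail (scipy), BH adjustment via statsmodels, ranking by raw p with
deterministic tie-breaks (larger overlap, then term id). The background
universe defaults to the union of the library's genes and is
configurable; query genes outside the universe are dropped with a
warning. No composite "combined score" (log-p × z-deviation style) is
computed: such scores depend on precomputed background ensembles of the
hosting service, while plain Fisher + BH is self-contained and
reproducible. The retention p-threshold is a parameter (default 0.05).

## D-H-C-T-P assembly

The five layers are strictly ordered (drug → herb → compound → target →
pathway) and edges may only connect adjacent layers — enforced by the
container, not just by construction. Node ids are layer-prefixed so a
compound and a gene may share a display name. Compound–target edges are
restricted to the screened core genes; compounds without a core-gene
target (and herbs left empty) are omitted by default, since they carry
no information in the reduced network. Pathway membership is an input
table (typically from the enrichment stage), not a live lookup.
Exports: SIF, GraphML and a node/edge TSV pair, all lossless for ids,
layers and edges. GraphML output is verified by XML parsing and
read-back identity.

## The synthetic-data generators

All generators are pure functions of a spec that includes the integer
seed (numpy `default_rng`); identical calls produce byte-identical
files. Gene symbols are synthetic tokens `G000001…` except the six
labelled hubs of the 40-node fixture.

**Planted-core PPI network** (default 300 nodes, 6-node core,
attachment fraction 0.4, background edge probability 0.01): the core is
a clique; every core member attaches to one shared random sample of
⌈0.4·294⌉ = 118 periphery nodes; background edges are independent
Bernoulli(0.01); stray components are wired to a random core node so
closeness stays well-defined. The *shared* attachment neighbourhood is
a deliberate design choice: hub cores in real PPI data (protein
complexes, signalling modules) share interaction partners, and the
shared neighbourhood keeps the core exactly symmetric in every induced
subgraph. With independent per-core attachment samples, late screening
rounds can leave pendant periphery nodes attached to only part of the
core; clique members without pendants then have betweenness 0 and are
cut by the strict mean rule, so the screen would frequently converge
inside the true core. Under the shared design the screen recovers the
planted core exactly in 100/100 seeds at the default parameters (the
test suite requires ≥ 95/100).

**40-node hub network**: one universal node (degree 39, closeness
exactly 1), three degree-36 hubs (a mutual triangle plus 33 of the 34
filler nodes each; which filler is skipped varies with the seed), two
degree-35 hubs (all 34 fillers), plus random filler–filler padding.
The universal node pins all distances ≤ 2, forcing the labelled
closeness values to 39/39, 39/42 = 0.928571429 and 39/43 = 0.906976744
for every seed.

**Compound–target study**: default conditions are a nine-herb
formulation with per-herb compound counts (6, 20, 5, 17, 34, 83, 17,
5, 5), a 20 000-gene universe (human protein-coding scale), an
8886-gene disease set, 5–25 targets per compound, and disease-gene
sampling weight 1.2 — which puts the per-target disease-hit rate near
0.49, the scale observed in real curated studies of this design. At
weight 1 the disease set is independent of the targets, so the overlap
of the target union with the disease set has exactly the
hypergeometric expectation `n·K/N` (verified over 200 seeds). Every
compound receives ≥ 1 target, so the target-less-exclusion rule is
exercised in tests by deleting map entries.

**Annotation libraries**: terms are uniform draws from the universe;
planted terms over-sample a designated query set with a configurable
weight. At weight 1 every term is an exact hypergeometric null draw,
which is what the type-I calibration tests exploit: the empirical
fraction of terms with p < 0.05 is compared, to binomial 3σ accuracy,
with the *analytically computed* null rejection probability (itself
≤ 0.05 — Fisher's exact test is conservative under discreteness, so
"≈ 5 %" means the attainable sub-5 % rate, not 5 % exactly).

What the generators do **not** emulate: realistic PPI degree
distributions beyond "sparse background + dense core", correlated or
hierarchical annotation terms (no GO DAG), compound chemistry, or
expression data. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the planted models, not
fidelity to any particular organism's interactome.

## Problem sizes

The routine test suite runs the full 100-seed planted-core recovery
experiment (300-node graphs), 100-graph oracle comparisons at n ≤ 8,
exhaustive hypergeometric enumeration at N ≤ 12, and 200-seed
calibration runs — sizes chosen so the complete suite finishes in
about a minute on one CPU while keeping every statistical check at
meaningful resolution.

## Known limitations

- No alias/identifier resolution for gene symbols.
- Hub screening significance is not assessed (no null-model p-value
  for "core-ness"); the audit trail is descriptive.
- Printed third- and fourth-round thresholds of historical analyses
  cannot generally be re-derived from counts alone, because the
  intermediate node sets are not recoverable; only the `2E/N` identity
  of a known round is auditable.
- The multipartite network carries no edge weights (e.g. binding
  affinities); docking and co-expression integration are out of scope.
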