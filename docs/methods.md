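# Methods

## Networks

The **true PPIN** is an undirected simple graph whose nodes are all proteins
appearing in the score-filtered interaction records and whose edges are the
recorded interactions. Nodes carry a role label: TARGET if the identifier is
in the user-supplied target list, INTERACTOR otherwise. Records are parsed
from the STRING `protein.links` dialect (protein1, protein2, integer
combined score in (0, 1000]); pairs present in both orientations collapse to
one edge keeping the maximum score (STRING files list both directions; the
maximum is the conservative choice). Self-interactions are rejected at
parse. The default score threshold is 300, kept inclusively: a pair scoring
exactly 300 survives, pairs *below* 300 are removed.

The **false PPIN** shares the node set; its edges are pairs (u, v) with u a
TARGET node and (u, v) not an edge of the true network. The complete set of
such non-edges is O(|targets|·|nodes|) and dwarfs the true edge set, so the
default samples exactly |E(true)| of them uniformly without replacement
(balanced classes for the downstream two-sample tests and classifiers); the
full complement is available behind `n_false_edges="all"`. Non-edges between
two interactors are excluded — the false network contrasts *target-incident*
interactions specifically. Target–target non-edges are counted once.

## Edge and node attributes

Link-prediction scores for a pair (u, v), neighbourhoods excluding the
endpoints themselves:

- Jaccard: |N(u) ∩ N(v)| / |N(u) ∪ N(v)| (0 on empty union);
- preferential attachment: deg(u)·deg(v);
- common neighbours: |N(u) ∩ N(v)|;
- resource allocation: Σ_{z ∈ N(u)∩N(v)} 1/deg(z). A common neighbour is
  adjacent to both endpoints, so deg(z) ≥ 2 and the division is always
  defined (asserted, not guarded).

Scores for false pairs are computed on the **true network's topology** (the
false pair itself contributes no edge), the standard link-prediction
convention.

Node attributes: degree; closeness centrality in the component-scaled
Wasserman–Faust form ((n_c−1)/(N−1)) · ((n_c−1)/Σd) so values stay in [0, 1]
and comparable on disconnected graphs (the false and pruned networks
typically are); Brandes shortest-path betweenness normalized by
(N−1)(N−2)/2 with endpoints excluded; local clustering coefficient (0 for
degree < 2); eccentricity per connected component (0 for isolated nodes);
and eigenvector centrality as the principal adjacency eigenvector,
non-negative, unit Euclidean norm.

Eigenvector centrality is computed by power iteration on A + I (same
eigenvectors as A; the shift makes the principal eigenvalue strictly
dominant even on bipartite components, which would otherwise oscillate).
Defaults: tolerance 1e−8 in max-norm change, 1000 iterations, uniform start;
non-convergence raises an error naming the budget. On disconnected graphs
each component with an edge is iterated separately and the component with
the largest principal eigenvalue carries the vector (all other nodes get
0); a numerically degenerate principal eigenvalue across components is
resolved in favour of the largest component, with a logged warning.

## Attribute selection

Edge attributes are compared between true and false networks with Welch's
unequal-variance t-test (two-sided, Welch–Satterthwaite degrees of
freedom). Welch rather than Student's pooled test because the group
variances of topological scores differ grossly in practice. The four tests
are Bonferroni-adjusted (m = 4); results sort by ascending adjusted p, and
the top attribute is reported as discriminating (none when no test reaches
adjusted p < 1). Pearson correlations of the STRING combined score against
each edge attribute, and the 6×6 node-attribute correlation matrix, use the
standard product-moment coefficient; a constant attribute yields an
undefined (NaN) row/column rather than an error.

Node attributes are ranked by two classifiers fit to origin labels
(true-network rows vs false-network rows): a ridge-penalized logistic
regression (penalty weight C = 1.0) on standardized features, importance =
|standardized coefficient|; and a 200-tree random forest with seeded
bootstrap, importance = mean impurity decrease. Attributes are aggregated
by mean rank across the two methods, ties broken by the linear importance.
The separation score is the stratified 5-fold cross-validated ROC AUC of
the logistic model on all six attributes. Rows are treated as independent
samples (the same protein contributes one row per network).

## Pruning

Cutoffs are linear-interpolation percentiles (position (q/100)·(n−1) on the
sorted values — the common numerical-stack default), computed **once on the
un-pruned true network**. Rules apply in order: remove edges with Jaccard
score strictly *above* the 75th-percentile cutoff; remove nodes with
closeness strictly *below* the 25th-percentile cutoff (with incident
edges); remove nodes left isolated. Strict inequalities match the rules
"above"/"less than"; ties at a cutoff survive. Re-applying the rules with
the same precomputed cutoffs is a no-op (idempotence).

Removing *high*-Jaccard edges is deliberate and is implemented exactly as
published, although the Jaccard score is the attribute *enriched* in true
edges, so the rule removes many of the most "true-like" edges; a
`remove_high_edges=False` flag inverts the direction for sensitivity
analysis. Closeness values are not recomputed between the edge and node
rules (pre-pruning values are used for both).

## Markov clustering

The transition matrix is the adjacency matrix plus self-loops of weight 1
(canonical MCL practice, preventing parity oscillation on bipartite
structure), columns normalized to sum 1. Each MCL round: expansion (matrix
power, default e = 2), inflation (entry-wise power, default r = 2.0, then
column renormalization), pruning of entries below 1e−5. Iteration stops
when the max-norm change falls below 1e−8 or after 100 rounds (best-effort
result flagged non-converged, with a warning). Dense arrays are used up to
3,000 nodes and CSR sparse matrices above, with identical results to within
numerical tolerance (tested).

Clusters are read off the converged matrix: attractors are rows with
positive diagonal mass; each node joins the attractor row holding its
column's maximum (ties to the smallest row index); attractor rows sharing
support merge by connected components, guaranteeing a hard partition.
Cluster ids are ordered by descending size, then lexicographically smallest
member. Inflation is the resolution knob: lower values toward 1 merge
clusters, higher values split them (tested monotone on a planted-partition
graph at r ∈ {1.4, 2.0, 4.0}).

## Overrepresentation analysis

For each cluster and each pathway it overlaps (k ≥ 1), the one-sided
upper-tail hypergeometric probability P(X ≥ k), X ~ Hypergeom(N, K, n), is
computed with N the universe size, K the pathway size and n the cluster's
genes in the universe. The universe defaults to the union of all GMT
members; a user-supplied universe overrides it. Benjamini–Hochberg q-values
are computed across the full family of (cluster, pathway) tests; a pathway
is significant in a cluster iff q ≤ α (default 0.05). Pathways significant
in ≥ 2 and ≥ 3 clusters are summarized separately. All cluster members
(targets and interactors) are tested; an optional two-column id map
translates protein ids to gene symbols first. Restricting tests to k ≥ 1
reduces the family size; a switch tests all pairs instead.

## Synthetic data

`generate_network` draws a planted-partition (stochastic block) graph:
nodes split into near-equal communities, within-community pairs connected
with probability p_in, between-community pairs with p_out, targets spread
evenly across communities. Edge scores are uniform integers on [150, 999];
within-community scores are shifted up by `score_bias` (default 200) and
clipped, reproducing the weak positive score–topology correlation regime of
real interactomes. Defaults — 6 communities × 20 nodes, 30 targets,
p_in = 0.6, p_out = 0.02 — give MCL-recoverable blocks at desk scale. The
block model is chosen because MCL's behaviour on it is well characterized
and community structure induces exactly the elevated shared-neighbour
statistics (Jaccard, resource allocation) on true edges that the analysis
relies on. It does **not** reproduce scale-free degree distributions,
hub proteins, or annotation noise of real interactomes, so passing tests
demonstrate correctness of the machinery, not performance on real data.

`generate_pathways` samples background pathways uniformly from all nodes
and planted pathways from a home community. `planted_fraction` defaults to
1.0 (fully community-concentrated ground truth; lower it to study
degradation). The shared planted pathway spans three communities, covering
`planted_fraction` of *each*; its homes are the three communities with the
most between-community interactions when edge records are supplied —
module-spanning pathways belong to the modules that communicate, which are
also the modules best retained by closeness-based pruning. This
concentration level is a power requirement, not a tuning convenience: with
a 120-node universe and ~180 BH-corrected tests, post-pruning clusters of
10–20 nodes need per-cluster overlaps near the cluster size for the
planted signal to clear the FDR threshold at all; a pathway diluted across
three communities (a third of its members each) is statistically
undetectable at this scale.

`generate_false_attribute_fixture` produces paired node-attribute tables
in which only the closeness column separates the origins (by a chosen
number of standard deviations) — a controlled input for validating the
attribute-ranking machinery.

All generators are pure functions of their spec including the seed;
outputs are byte-identical across runs.

## Pipeline

Stages run in order build → attributes → selection → prune → cluster →
enrich; every intermediate table is written to the output directory and
the run report's counts equal recounts of those files (tested). One global
seed derives per-stage seeds as CRC32("stage:seed") so stages are
independently reproducible; two runs of the same configuration are
byte-identical apart from the report timestamp. A stage failure aborts with
the stage name, preserving partial outputs.

## Numerical and testing notes

- Column stochasticity is preserved to 1e−9 through every MCL round;
  partitions are asserted disjoint-and-covering on construction.
- Test-suite problem sizes: exhaustive metric-oracle agreement on every
  connected graph with ≤ 6 nodes plus 100 seeded random graphs with ≤ 40
  nodes; MCL dual-route agreement on 50 seeded random graphs; the
  hypergeometric tail is checked exhaustively for all valid (k, n, K, N)
  with N ≤ 25; the end-to-end run uses the default 120-node study
  conditions. These sizes keep the whole suite in the tens of seconds
  while leaving every code path exercised.
- Known limitations: no weighted-graph semantics beyond the score filter;
  no id mapping beyond the optional two-column file; eigenvector
  centrality on graphs whose two largest adjacency eigenvalues are nearly
  equal converges slowly (the iteration budget then needs raising); the
  edge-pruning direction follows the published rule even though it removes
  high-Jaccard (true-like) edges — see Pruning above.
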