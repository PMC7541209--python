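# netpharm

Network-pharmacology analysis of protein–protein interaction networks
(PPINs). Starting from a scored interaction edge list (STRING
`protein.links` dialect) and a list of target proteins (e.g. predicted
ligand targets of a set of bioactive compounds), the package

1. builds the **true PPIN** (targets + their interactors, edges with
   combined score ≥ 300) and a **false PPIN** (target-incident protein
   pairs with *no* recorded interaction) over the same node set;
2. computes four **link-prediction edge scores** — Jaccard coefficient,
   preferential attachment, common neighbours, resource-allocation index —
   and six **node attributes** — degree, closeness, eigenvector and
   betweenness centralities, local clustering coefficient, eccentricity;
3. **selects discriminating attributes**: Welch t-tests (Bonferroni m=4)
   contrast edge scores between the two networks, Pearson correlations
   relate them to the STRING score, and a ridge-penalized logistic
   regression plus a random forest rank node attributes by their power to
   tell true from false network topology;
4. **prunes** the true PPIN by percentile rules (drop edges with Jaccard
   score above the 75th percentile, then nodes with closeness below the
   25th percentile, then isolated nodes);
5. identifies protein modules with a from-scratch **Markov Cluster (MCL)
   algorithm** — alternating expansion `M ← M^e` and inflation
   `M_ij ← M_ij^r / Σ_i M_ij^r` of a column-stochastic transition matrix
   until idempotence, clusters read off the attractor structure;
6. tests each cluster for **pathway overrepresentation** (one-sided
   hypergeometric test `P(X ≥ k)`, X ~ Hypergeom(N, K, n), with
   Benjamini–Hochberg FDR across all cluster × pathway tests) and reports
   pathways significant in ≥ 2 and ≥ 3 clusters — the signature of a
   synergistic, multi-module mechanism.

A fully seeded synthetic-data module (planted-partition network with
STRING-style integer scores, target lists, GMT pathway sets with planted
community-concentrated pathways) generates every input the pipeline needs,
so the whole analysis is exercisable and testable at desk scale without any
external service.

## Worked example

```sh
netpharm simulate --outdir inputs --seed 1
netpharm run-all --links-file inputs/links.txt --targets-file inputs/targets.txt \
    --gmt-file inputs/pathways.gmt --output-dir run --seed 1
```

prints

```json
{
 "n_nodes": 120,
 "n_edges": 777,
 "n_clusters": 7,
 "best_edge_attribute": "jaccard",
 "best_node_attribute": "closeness",
 "n_pathways_shared_3plus": 1,
 "report": "run/report.json"
}
```

The synthetic interactome has 120 proteins in 6 communities and 777
score-filtered interactions. The Welch t-test ranks the Jaccard score as
the most discriminating edge attribute between true and false networks
(`run/selection.tsv`: t ≈ 43.9, adjusted p ≈ 2e-255), and the classifiers
rank closeness centrality as the best node attribute. After 75/25
percentile pruning, MCL finds 7 clusters (`run/cluster_summary.tsv`; the 6
planted communities plus one small fragment), and one pathway — the
planted module-spanning one — is significantly overrepresented in 3
clusters (`run/overlap.tsv`, pathway `PW000` in clusters 1, 2 and 4).

The same stages are available as library functions
(`netpharm.build_true_ppin`, `netpharm.cluster_network`,
`netpharm.enrich_clusters`, …) and as per-stage subcommands
(`simulate`, `build`, `score-edges`, `score-nodes`, `select`, `prune`,
`cluster`, `enrich`). MCL is also exposed as a scikit-learn-style
estimator, `netpharm.MarkovClustering`.

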