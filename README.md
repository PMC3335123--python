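# coexnet

Consensus gene co-expression network analysis for multi-study expression
data, built around the workflow used to characterise the transcriptome of
heterogeneous diseases such as hepatocellular carcinoma: infer a relevance
network per study, keep the links that recur in every study, and show that
this consensus is non-random, topologically structured, and functionally
coherent.

## What it computes

Given expression matrices $X^{(s)} \in \mathbb{R}^{g \times n_s}$ (genes ×
samples, log-scale) for studies $s = 1 \dots S$:

1. **Relevance networks.** Gene pairs with Pearson correlation
   $r_{ij} \ge \tau$ become edges of an undirected, unweighted network.
   The threshold $\tau$ is selected automatically on the grid
   $0.50 \le \tau \le 1.00$: at each grid point the network's average
   clustering coefficient $\bar{C}$ is compared with the mean $\bar{C}$ of
   degree-preserving Maslov–Sneppen rewirings ($4{\times}|E|$ swap
   attempts), and the first local maximum of
   $\bar{C}_{\text{real}} - \bar{C}_{\text{random}}$ is chosen.
2. **Consensus network.** Edges present in all $S$ study networks; nodes
   are the endpoints of surviving edges.
3. **Significance.** The randomized-intersection null: each of $R$
   repetitions (default 200) rewires every study network independently and
   records the size of their intersection; the observed consensus is
   reported as $z = (\text{obs} - \mu_{\text{null}})/\sigma_{\text{null}}$.
4. **Topology.** Degree, unnormalized betweenness, clustering,
   assortativity, diameter of the largest component, giant-component
   fraction; discrete power-law fits $p(x) \sim x^{-\alpha}$, $x \ge
   x_{\min}$ by maximum likelihood with KS-selected $x_{\min}$ and a
   semi-parametric bootstrap goodness-of-fit p-value (power law plausible
   when $p > 0.1$); Wilcoxon rank-sum comparison of metric distributions
   between gene groups.
5. **Modules and function.** Louvain and Markov-Cluster (MCL)
   partitioning; functional coherence as the mean annotation-term Jaccard
   over co-expressed same-cluster gene pairs versus size-matched random
   partitions; hypergeometric term enrichment per cluster with
   Benjamini–Hochberg adjustment (terms filtered to 5–50 in-universe
   genes).

A synthetic-data module generates multi-study designs with planted shared
and study-private co-expression modules under a single-factor model, so
every stage is testable against a known ground truth without downloads.

## Worked example

```python
import coexnet as cx

cfg = cx.SyntheticConfig(seed=1)        # 3 studies, one shared 20-gene module
studies, truth = cx.generate_multi_study(cfg)
nets = [cx.build_network(cx.correlation_matrix(m), 0.7) for m in studies]
consensus = cx.intersect_networks(nets)
null_genes, null_links = cx.intersection_null(nets, n_reps=200, seed=3)
print(consensus.number_of_nodes(), consensus.number_of_edges())
print(cx.zscore(consensus.number_of_edges(), null_links))
```

Running `python examples/01_simulate_and_recover.py` and
`python examples/03_consensus_significance.py` prints:

```
study1: 35 genes, 295 links
study2: 35 genes, 295 links
study3: 35 genes, 295 links
consensus: 20 genes, 190 links
shared-module link recall: 100.00%
private-module links in consensus: 0

observed consensus: 20 genes, 190 links
null links: mean 47.8, sd 4.3 (200 reps)
link z-score: 33.0
```

The consensus recovers exactly the 190 links of the planted shared module
(20 genes, $\binom{20}{2}$ pairs) and none of the study-private modules;
the z-score of 33 says a consensus of this size essentially never arises
from degree-preserving rewiring alone. The other scripts in `examples/`
walk through threshold selection, topology and power-law fitting, module
detection with coherence and enrichment, and the one-call pipeline.

## Command line

Each stage is also exposed as a thin CLI:

```bash
coexnet simulate --seed 1 --out sim/
coexnet infer --expr sim/expr_study1.tsv --seed 1 --out net1.edges --scan scan1.tsv
coexnet consensus --nets net1.edges net2.edges net3.edges --out conserved.edges
coexnet nullcheck --nets net1.edges net2.edges net3.edges --reps 200 --seed 1 --out null.json
coexnet topology --net conserved.edges --powerlaw --nboot 1000 --seed 1 --out metrics.json
coexnet cluster --net conserved.edges --method louvain --seed 1 --out partition.tsv
coexnet enrich --partition partition.tsv --net conserved.edges --gmt sim/annotations.gmt --out enrich.tsv
coexnet run --config cfg.yaml --out results/
```

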