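# Methods

This note documents the models, defaults, and numerical choices behind
`coexnet`, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic multi-study generator

**Model.** Gene expression is simulated under a single-factor model per
module: gene $g$ in module $m$ has
$x_g = w f_m + \varepsilon_g$ with $f_m \sim N(0,1)$ drawn fresh per
study, $\varepsilon_g \sim N(0, \sigma_e^2)$ independent, and
$w = \sigma_e \sqrt{\rho/(1-\rho)}$, so the population correlation of any
within-module pair is exactly the target $\rho$. Genes outside modules
are independent noise. Only this second-moment structure matters to a
correlation-thresholding pipeline, so no attempt is made to model
probe-level effects, batch effects, heavy-tailed intensities, or
normalisation artifacts of real microarray data. Passing tests therefore
demonstrate correctness of the network machinery under the assumed
correlation structure, not robustness to array-specific noise.

**Defaults.** Three studies, 100 genes, 100 samples per study, one shared
module (20 genes, $\rho = 0.9$) and one study-private module (15 genes,
$\rho = 0.9$) per study, unit noise SD. These are the conditions under
which a consensus pipeline should recover shared structure essentially
completely: at $n = 100$ samples the sampling SD of a pair correlation
around $\rho = 0.9$ is about $(1-\rho^2)/\sqrt{n} \approx 0.02$, so a
threshold of 0.7 sits many SDs below the planted correlation and many SDs
above the noise-correlation band ($\approx 0.1$ SD around 0).

**Labels and RNG.** Shared-module genes carry identical labels in every
study (`Gs1_1`, ...); private modules carry study-specific labels
(`Gp2.1_1`, ...) and therefore cannot recur across studies by
construction; fill-in noise genes (`N1`, ...) are measured in every study
but drawn independently. Each study uses an RNG stream derived from
`(seed, study_index)`, so extending a design with more studies never
perturbs the data of earlier ones.

**Degenerate settings.** `noise_sd = 0` or `within_corr = 1` plant an
exactly rank-1 block (all pairwise correlations 1). `within_corr` is
accepted on $(0, 1]$ for this reason.

## Threshold selection

The scan covers $0.50 \le \tau \le 1.00$ with step 0.01 by default (the
resolution at which the curves are informative; coarser steps are fine
for small fixtures). At each grid point the thresholded network's average
clustering coefficient is compared with the mean over $R = 10$
Maslov-Sneppen rewirings; a single rewired instance would be noisier, and
10 replicates stabilise the difference curve at modest cost. Grid points
whose network has fewer than 3 edges record a difference of 0 and are
flagged rather than dropped, keeping the grid rectangular. Selection
takes the first interior local maximum of the difference (strictly rising
into the point, non-rising out of it); if the difference is monotone the
argmax is returned with a `fallback` flag, and an all-flat difference is
an error rather than a silent arbitrary pick.

Thresholding is signed by default (edge iff $r \ge \tau$), reading
"correlated above a threshold" literally; an `absolute` mode
($|r| \ge \tau$) is available since negative co-expression can be of
interest. Isolated genes are excluded from the node set: a relevance
network is defined by its links.

## Maslov-Sneppen rewiring

Each attempt picks two distinct edges $(a,b), (c,d)$ with random
orientation and proposes $(a,d), (c,b)$. Proposals creating self-loops or
multi-edges are rejected *but counted* toward the budget of $4{\times}|E|$
attempts — attempt counting is the common convention and makes the
procedure's cost predictable; rejected swaps leave the graph unchanged.
The output always has exactly the input degree sequence and is always
simple. Graphs admitting no valid swap (e.g. a triangle, whose degree
sequence has a unique simple realisation) come back as a copy flagged
`saturated`.

The randomized-intersection null rewires every input network
independently in each of 200 repetitions (one RNG substream per
(network, repetition), so results are order-stable) and records the
intersection's link count and gene count. The gene count of an
intersection is defined as the number of distinct endpoints of surviving
shared links: isolated shared labels carry no co-expression evidence. In
benchmarks, the *link* z-score is the sensitive statistic — with planted
shared modules the high-degree module genes still attract intersecting
edges after rewiring, so the gene count is a much weaker signal.

## Topology

Betweenness is unnormalized shortest-path pair counting; all rank-sum
comparisons of metric distributions are scale-invariant, so the
normalisation convention does not affect conclusions. Average clustering
counts degree-<2 nodes as 0 (the usual convention). Assortativity is the
Pearson correlation of endpoint degrees over both edge orientations and
is reported as undefined — not 0 — when all degrees are equal. The
diameter is computed on the largest connected component, the only
well-defined choice for fragmented consensus networks; the
giant-component fraction reports that fragmentation separately.

The rank-sum test enumerates all rank assignments exactly (with midranks
for ties) when the pooled sample has ≤ 20 observations and uses the
tie-corrected normal approximation above that.

## Power-law fitting

Discrete (integer) formulation: the tail CDF is normalised by the Hurwitz
zeta function $\zeta(\alpha, x_{\min})$, and the exponent uses the
continuous-approximation MLE
$\hat\alpha = 1 + n_{\text{tail}} \big[\sum_i \ln\!\big(x_i/(x_{\min} -
\tfrac12)\big)\big]^{-1}$, which is the exact MLE of a continuous power
law on $[x_{\min} - \tfrac12, \infty)$ — the test suite checks it against
a dense-grid maximization of that likelihood. $x_{\min}$ is chosen to
minimise the KS distance between empirical and fitted tail CDFs over the
observed unique values. The goodness-of-fit p-value is semi-parametric
bootstrap (default 1000 replicates): resample the head empirically,
sample the tail from the fitted law (exact inverse-CDF sampling through
the zeta-normalised survival function), refit from scratch, and count
replicates whose KS distance exceeds the observed one; the power law is
considered plausible when $p > 0.1$. Calibration on exact power-law
samples gives $p > 0.1$ in ~90% of seeds, as expected for a
uniform-under-null p-value.

## Modules and function

Louvain partitioning delegates to networkx's implementation with a seeded
node order; cluster ids are deterministic (decreasing size, ties by
smallest label). MCL is implemented directly: unit self-loops,
column-stochastic normalisation, then expansion (matrix squaring) and
inflation (entrywise power $r$, default 2.0, then renormalisation) until
the matrix changes by less than $10^{-8}$ or 200 iterations (flagged if
hit); clusters are read from overlapping attractor rows. Entries below
$10^{-14}$ are pruned each iteration to stabilise convergence. Cluster
counts of both algorithms are implementation- and parameter-dependent, so
published cluster counts for real networks are not asserted by tests.

Functional coherence scores *co-expressed* same-cluster pairs — network
edges whose endpoints share a cluster and both carry at least one
annotation term — by the Jaccard coefficient of their term sets. The
baseline permutes gene labels across cluster slots (size multiset
preserved exactly) rather than rewiring the network, the more direct
reading of "random clusters with identical numbers of genes and links";
a rewiring alternative can be composed from `maslov_sneppen` if wanted.
The fold statistic only separates real from random partitions when the
network contains low-similarity (cross-module) edges a good partition can
exclude — on a network consisting solely of within-module links every
eligible pair is similar and the fold is ~1 by construction; benchmark
fixtures therefore include cross-module edges. Annotation terms are
filtered to 5–50 genes *after* restriction to the analysis universe
(boundaries inclusive); unannotated genes are ineligible for Jaccard
pairs but remain in the enrichment reference.

Enrichment p-values are upper-tail hypergeometric probabilities computed
with scipy's stable survival function; Benjamini-Hochberg adjustment is
applied per cluster across its tested terms by default (a global switch
exists). All network genes form the reference.

## Pipeline and reproducibility

The pipeline is driven by a single config (YAML-compatible); every source
of randomness is a named seed recorded in the output manifest, and
re-running a config is byte-identical. Stage failures abort with a
stage-tagged error while earlier outputs remain on disk. A
`drop_sample_prefix` option re-runs the identical pipeline on a sample
subset (e.g. tumor-only), supporting conserved-vs-tumor-consensus
comparisons via `partition_overlap_jaccard`; no special code path exists
for that analysis.

## Problem sizes in tests and benchmarks

Benchmarks use designs of 60–100 genes, 3 studies, and 60–100 samples,
with 200 randomization repetitions and up to 1000 bootstrap replicates —
sizes at which every property under test (recovery, null separation,
calibration) is already unambiguous while the full suite runs in minutes
on one CPU. The machinery itself is dense-matrix based and comfortable up
to a few thousand genes per study.

## Known limitations

- The generator does not simulate probe-level effects, batch structure,
  clinical covariates, or platform differences; see above for what this
  implies about test evidence.
- MCL uses dense matrices; very large networks would need a sparse
  implementation.
- The continuous-approximation exponent MLE is least accurate for
  $x_{\min} = 1$ heavy-tailed samples (a known property of the
  approximation); the bootstrap uses the same estimator throughout, so
  goodness-of-fit calibration is unaffected.
- Exact rank-sum enumeration is limited to pooled samples of 20; larger
  samples use the asymptotic approximation.
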