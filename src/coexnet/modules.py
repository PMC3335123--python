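"""Module detection and functional assessment.

Partitions a co-expression network into gene modules with either Louvain
modularity optimization or the Markov Cluster Algorithm (MCL), scores a
partition's functional coherence as the mean annotation-term Jaccard over
co-expressed (edge-connected) same-cluster gene pairs against size-matched
random partitions, and evaluates per-cluster hypergeometric enrichment
with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coexnet.io import AnnotationCatalog


@dataclass
class Partition:
    """Gene -> cluster assignment, optionally with its modularity Q."""

    assignment: dict
    modularity: float | None = None
    flags: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def sizes(self) -> list[int]:
        return sorted((len(m) for m in self.clusters().values()), reverse=True)

    def clusters(self) -> dict:
        out: dict = {}
        for g, c in self.assignment.items():
            out.setdefault(c, set()).add(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items(), key=lambda kv: (kv[1], str(kv[0]))),
            columns=["gene", "cluster"],
        )


def _partition_from_communities(net: nx.Graph, communities) -> Partition:
    # deterministic cluster ids: 1..k by decreasing size, ties by smallest label
    ordered = sorted(communities, key=lambda c: (-len(c), min(str(v) for v in c)))
    assignment = {v: cid for cid, comm in enumerate(ordered, start=1) for v in comm}
    q = float(nx.community.modularity(net, ordered)) if net.number_of_edges() else 0.0
    return Partition(assignment=assignment, modularity=q)


def louvain_partition(net: nx.Graph, seed: int = 0) -> Partition:
    """Louvain greedy modularity optimization (node order seeded)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comms = nx.community.louvain_communities(net, seed=seed)
    return _partition_from_communities(net, comms)


def mcl_partition(net: nx.Graph, inflation: float = 2.0,
                  max_iter: int = 200, tol: float = 1e-8) -> Partition:
    """Markov Cluster Algorithm on the network's stochastic flow matrix.

    Adds unit self-loops, column-normalizes the adjacency matrix, then
    alternates expansion (matrix squaring) and inflation (entrywise power
    ``inflation`` followed by column renormalization) until the matrix is
    stable to ``tol`` or ``max_iter`` is hit (the latter flags the result
    as non-converged).  Clusters are read from the attractor structure of
    the limit matrix; the procedure is fully deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(net.nodes(), key=str)
    a = nx.to_numpy_array(net, nodelist=nodes, dtype=float)
    np.fill_diagonal(a, a.diagonal() + 1.0)
    m = a / a.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        m2 = m @ m
        m2 = np.power(m2, inflation)
        colsum = m2.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m2 /= colsum
        m2[m2 < 1e-14] = 0.0  # prune numerical dust to stabilise convergence
        m2 /= m2.sum(axis=0, keepdims=True)
        if np.max(np.abs(m2 - m)) < tol:
            m = m2
            converged = True
            break
        m = m2

    thr = 1e-6
    n = len(nodes)
    # attractors are rows with support; overlapping attractor rows merge
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    attractors = [i for i in range(n) if m[i].max() > thr]
    owner = {}
    for i in attractors:
        for j in np.flatnonzero(m[i] > thr):
            if j in owner:
                union(i, owner[j])
            else:
                owner[j] = i
    assignment_idx = {}
    for j in range(n):
        if j in owner:
            assignment_idx[j] = find(owner[j])
        else:  # no supporting attractor (numerically starved column)
            assignment_idx[j] = find(int(np.argmax(m[:, j])))
    groups: dict = {}
    for j, root in assignment_idx.items():
        groups.setdefault(root, set()).add(nodes[j])
    part = _partition_from_communities(net, list(groups.values()))
    part.flags["converged"] = converged
    return part


def filter_terms(cat: AnnotationCatalog, universe, min_size: int = 5,
                 max_size: int = 50) -> AnnotationCatalog:
    """Drop terms whose in-universe size falls outside [min_size, max_size].

    Sizes are counted after restriction to the gene universe, and the
    retained gene sets are the restricted ones; the boundaries are
    inclusive.
    """
    universe = frozenset(universe)
    terms = {}
    names = {}
    for tid, genes in cat.terms.items():
        restricted = genes & universe
        if min_size <= len(restricted) <= max_size:
            terms[tid] = frozenset(restricted)
            names[tid] = cat.names.get(tid, tid)
    return AnnotationCatalog(terms=terms, names=names, namespace=cat.namespace)


@dataclass
class JaccardResult:
    """Mean pairwise term-set Jaccard over eligible co-expressed pairs."""

    mean: float | None  # None when no eligible pair exists
    n_pairs: int


def pairwise_functional_jaccard(net: nx.Graph, p: Partition,
                                cat: AnnotationCatalog) -> JaccardResult:
    """Functional similarity of co-expressed same-cluster gene pairs.

    For every network edge whose endpoints share a cluster and both carry
    at least one annotation term, the Jaccard coefficient of their term
    sets is computed; the mean over eligible pairs is returned (undefined,
    not 0, when no pair is eligible).
    """
    g2t = cat.gene_to_terms()
    total = 0.0
    n_pairs = 0
    for a, b in net.edges():
        if p.assignment.get(a) != p.assignment.get(b):
            continue
        if p.assignment.get(a) is None:
            continue
        ta, tb = g2t.get(a), g2t.get(b)
        if not ta or not tb:
            continue
        total += len(ta & tb) / len(ta | tb)
        n_pairs += 1
    return JaccardResult(mean=total / n_pairs if n_pairs else None, n_pairs=n_pairs)


@dataclass
class CoherenceResult:
    """Real-vs-random functional coherence of a partition."""

    fold: float
    p_empirical: float
    real_mean: float
    random_means: np.ndarray
    n_pairs: int


def coherence_vs_random(net: nx.Graph, p: Partition, cat: AnnotationCatalog,
                        n_random: int = 100, seed: int = 0) -> CoherenceResult:
    """Coherence fold of a partition against size-matched random partitions.

    ``fold`` is the real mean pairwise Jaccard divided by the mean over
    ``n_random`` label-permuted partitions with the identical cluster-size
    multiset; the empirical p-value is the fraction of random means that
    reach the real mean.  Random partitions with no eligible pair score 0.
    """
    from coexnet.nulls import random_partition

    real = pairwise_functional_jaccard(net, p, cat)
    if real.mean is None:
        raise ValueError("no eligible annotated co-expressed pairs in the real partition")
    rng = np.random.default_rng(seed)
    means = np.empty(n_random)
    for i in range(n_random):
        rp = random_partition(p, rng=rng)
        res = pairwise_functional_jaccard(net, rp, cat)
        means[i] = 0.0 if res.mean is None else res.mean
    rand_mean = float(means.mean())
    fold = np.inf if rand_mean == 0 else real.mean / rand_mean
    p_emp = float(np.mean(means >= real.mean))
    return CoherenceResult(fold=float(fold), p_empirical=p_emp,
                           real_mean=real.mean, random_means=means,
                           n_pairs=real.n_pairs)


def hypergeometric_enrichment(cluster, cat: AnnotationCatalog,
                              reference) -> pd.DataFrame:
    """Hypergeometric over-representation of catalog terms in a gene cluster.

    For a cluster of n genes and a term with K genes in a reference of N,
    the p-value is the upper tail P(X >= k) of Hypergeometric(N, K, n) at
    the observed overlap k; q-values are Benjamini-Hochberg across the
    terms tested for this cluster.  Terms with no reference gene are
    skipped.
    """
    cluster = set(cluster)
    reference = set(reference)
    if not cluster <= reference:
        raise ValueError("cluster must be a subset of the reference gene set")
    n = len(cluster)
    big_n = len(reference)
    rows = []
    for tid in sorted(cat.terms):
        term_genes = cat.terms[tid] & reference
        big_k = len(term_genes)
        if big_k == 0:
            continue
        k = len(term_genes & cluster)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": tid, "name": cat.names.get(tid, tid),
                     "n": n, "K": big_k, "k": k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "name", "n", "K", "k", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = []
    return df


def enrich_partition(p: Partition, cat: AnnotationCatalog, reference,
                     min_cluster_size: int = 1,
                     bh_scope: str = "cluster") -> pd.DataFrame:
    """Enrichment table over all clusters of a partition.

    ``bh_scope='cluster'`` adjusts p-values within each cluster (the
    default); ``'global'`` re-adjusts across every (cluster, term) test.
    """
    if bh_scope not in ("cluster", "global"):
        raise ValueError("bh_scope must be 'cluster' or 'global'")
    frames = []
    for cid, members in sorted(p.clusters().items(), key=lambda kv: str(kv[0])):
        if len(members) < min_cluster_size:
            continue
        df = hypergeometric_enrichment(members & set(reference), cat, reference)
        df.insert(0, "cluster", cid)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["cluster", "term", "name", "n", "K", "k", "p", "q"])
    out = pd.concat(frames, ignore_index=True)
    if bh_scope == "global" and len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
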