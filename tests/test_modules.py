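"""Partitioning, term filtering, coherence, and enrichment."""

import math

import networkx as nx
import numpy as np
import pytest

from coexnet import (
    coherence_vs_random,
    filter_terms,
    hypergeometric_enrichment,
    louvain_partition,
    mcl_partition,
    modularity,
    pairwise_functional_jaccard,
)
from coexnet.io import AnnotationCatalog
from coexnet.modules import Partition, enrich_partition


def make_catalog(**terms):
    return AnnotationCatalog(terms={k: frozenset(v) for k, v in terms.items()})


class TestLouvain:
    def test_two_disjoint_cliques_split_at_half_modularity(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        p = louvain_partition(g, seed=1)
        assert p.n_clusters == 2
        assert p.modularity == pytest.approx(0.5)

    def test_complete_graph_is_one_cluster(self):
        p = louvain_partition(nx.complete_graph(8), seed=0)
        assert p.n_clusters == 1

    def test_ring_of_cliques_recovers_the_cliques(self, ring_of_cliques):
        p = louvain_partition(ring_of_cliques, seed=0)
        assert p.n_clusters == 4
        assert sorted(p.sizes) == [5, 5, 5, 5]

    def test_seed_reproducibility_and_q_stability(self, ring_of_cliques):
        p1 = louvain_partition(ring_of_cliques, seed=3)
        p2 = louvain_partition(ring_of_cliques, seed=3)
        assert p1.assignment == p2.assignment
        qs = [louvain_partition(ring_of_cliques, seed=s).modularity for s in range(5)]
        assert max(qs) - min(qs) < 0.02

    def test_q_matches_independent_recomputation(self, ring_of_cliques):
        p = louvain_partition(ring_of_cliques, seed=0)
        assert p.modularity == pytest.approx(modularity(ring_of_cliques, p), abs=1e-10)


class TestMCL:
    def test_disjoint_triangles_cannot_mix(self, two_triangles):
        p = mcl_partition(two_triangles)
        assert p.n_clusters == 2
        assert p.flags["converged"]

    def test_bridged_cliques_split_at_the_bridge(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        p = mcl_partition(g, inflation=2.0)
        clusters = sorted(sorted(c) for c in p.clusters().values())
        assert clusters == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_deterministic(self, ring_of_cliques):
        p1 = mcl_partition(ring_of_cliques)
        p2 = mcl_partition(ring_of_cliques)
        assert p1.assignment == p2.assignment

    def test_inflation_granularity_never_decreases_cluster_count(self):
        fixtures = [
            nx.ring_of_cliques(4, 5),
            nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4)),
            nx.planted_partition_graph(3, 8, 0.8, 0.1, seed=1),
        ]
        for g in fixtures:
            counts = [mcl_partition(g, inflation=r).n_clusters
                      for r in (1.5, 2.0, 3.0, 5.0)]
            assert counts == sorted(counts)

    def test_invalid_inflation_rejected(self, two_triangles):
        with pytest.raises(ValueError, match="inflation"):
            mcl_partition(two_triangles, inflation=1.0)


class TestFilterTerms:
    universe = frozenset(f"g{i}" for i in range(100))

    def test_boundaries_inclusive(self):
        cat = make_catalog(
            tiny=[f"g{i}" for i in range(4)],
            atmin=[f"g{i}" for i in range(5)],
            atmax=[f"g{i}" for i in range(50)],
            big=[f"g{i}" for i in range(51)],
        )
        out = filter_terms(cat, self.universe)
        assert set(out.terms) == {"atmin", "atmax"}

    def test_size_counted_in_universe(self):
        # 60-gene term, 40 inside the universe: kept after restriction
        genes = [f"g{i}" for i in range(40)] + [f"x{i}" for i in range(20)]
        out = filter_terms(make_catalog(t=genes), self.universe)
        assert set(out.terms) == {"t"}
        assert len(out.terms["t"]) == 40


class TestPairwiseFunctionalJaccard:
    def build(self, terms_by_gene):
        net = nx.Graph([("a", "b")])
        p = Partition({"a": 1, "b": 1})
        terms = {}
        for g, ts in terms_by_gene.items():
            for t in ts:
                terms.setdefault(t, set()).add(g)
        cat = AnnotationCatalog(terms={k: frozenset(v) for k, v in terms.items()})
        return net, p, cat

    @pytest.mark.parametrize("ta, tb, expected", [
        (("A", "B", "C"), ("A", "B", "C"), 1.0),
        (("A", "B", "C"), ("B", "C", "D"), 0.5),
        (("A", "B"), ("C", "D"), 0.0),
    ])
    def test_jaccard_of_term_sets(self, ta, tb, expected):
        net, p, cat = self.build({"a": ta, "b": tb})
        res = pairwise_functional_jaccard(net, p, cat)
        assert res.n_pairs == 1
        assert res.mean == pytest.approx(expected)

    def test_cross_cluster_and_unannotated_pairs_ineligible(self):
        net = nx.Graph([("a", "b"), ("b", "c")])
        p = Partition({"a": 1, "b": 2, "c": 2})
        cat = make_catalog(T=["a", "b"])
        res = pairwise_functional_jaccard(net, p, cat)  # b-c: c unannotated
        assert res.n_pairs == 0 and res.mean is None


class TestCoherence:
    @staticmethod
    def planted_fixture(seed=0):
        """ER network over 6 planted 10-gene modules with module terms."""
        rng = np.random.default_rng(seed)
        genes = [f"m{k}_{i}" for k in range(6) for i in range(10)]
        net = nx.Graph()
        net.add_nodes_from(genes)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.uniform() < 0.25:
                    net.add_edge(genes[i], genes[j])
        p = Partition({g: int(g[1]) for g in genes})
        terms = {f"T{k}": frozenset(g for g in genes if g.startswith(f"m{k}_"))
                 for k in range(6)}
        cat = AnnotationCatalog(terms=terms)
        return net, p, cat

    def test_planted_partition_beats_random(self):
        net, p, cat = self.planted_fixture()
        res = coherence_vs_random(net, p, cat, n_random=100, seed=1)
        assert res.fold > 2
        assert res.p_empirical < 0.05

    def test_partition_independent_annotations_give_unit_fold(self):
        net, p, _ = self.planted_fixture()
        folds = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            genes = list(net.nodes())
            # annotations drawn independently of the partition
            terms = {f"X{k}": frozenset(rng.choice(genes, size=12, replace=False))
                     for k in range(8)}
            cat = AnnotationCatalog(terms=terms)
            res = coherence_vs_random(net, p, cat, n_random=40, seed=seed)
            folds.append(res.fold)
        assert 0.8 < float(np.mean(folds)) < 1.25

    def test_planted_beats_random_across_seeds(self):
        # exhaustive-Jaccard oracle: planted partition strictly exceeds a
        # size-matched random partition's mean on every one of 20 seeds
        from coexnet.nulls import random_partition

        net, p, cat = self.planted_fixture()
        real = pairwise_functional_jaccard(net, p, cat).mean
        wins = 0
        for seed in range(20):
            rp = random_partition(p, seed=seed)
            rm = pairwise_functional_jaccard(net, rp, cat).mean or 0.0
            wins += real > rm
        assert wins == 20


class TestHypergeometricEnrichment:
    def test_cluster_equal_to_reference_forces_p_one(self):
        ref = {f"g{i}" for i in range(10)}
        cat = make_catalog(T1=list(ref)[:5], T2=list(ref)[3:9])
        df = hypergeometric_enrichment(ref, cat, ref)
        assert (df["k"] == df["K"]).all()
        assert np.allclose(df["p"], 1.0)

    def test_exact_tail_value(self):
        # N=10, K=5, n=4, k=4: p = C(5,4) C(5,0) / C(10,4) = 5/210
        ref = [f"g{i}" for i in range(10)]
        cat = make_catalog(T=ref[:5])
        df = hypergeometric_enrichment(set(ref[:4]), cat, ref)
        assert df.loc[0, "p"] == pytest.approx(5 / 210, abs=1e-12)

    def test_identical_pvalues_are_bh_fixed_point(self):
        ref = [f"g{i}" for i in range(12)]
        # three disjoint same-size terms with the same overlap pattern
        cat = make_catalog(T1=ref[0:4], T2=ref[4:8], T3=ref[8:12])
        df = hypergeometric_enrichment(set(ref[0:1] + ref[4:5] + ref[8:9]), cat, ref)
        assert df["p"].nunique() == 1
        assert np.allclose(df["q"], df["p"])

    def test_cluster_outside_reference_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment({"z"}, make_catalog(T=["a", "b"]), {"a", "b"})

    def test_pvalues_super_uniform_under_label_permutation(self):
        rng = np.random.default_rng(0)
        ref = [f"g{i}" for i in range(30)]
        cat = make_catalog(T=ref[:10])
        ps = []
        for _ in range(1000):
            cluster = set(rng.choice(ref, size=8, replace=False))
            df = hypergeometric_enrichment(cluster, cat, ref)
            ps.append(df.loc[0, "p"])
        ps = np.asarray(ps)
        for x in (0.05, 0.1, 0.25, 0.5):
            assert np.mean(ps <= x) <= x + 0.03

    def test_enrich_partition_scopes(self):
        ref = [f"g{i}" for i in range(20)]
        cat = make_catalog(T1=ref[:6], T2=ref[6:12])
        p = Partition({g: (1 if i < 10 else 2) for i, g in enumerate(ref)})
        local = enrich_partition(p, cat, ref, bh_scope="cluster")
        global_ = enrich_partition(p, cat, ref, bh_scope="global")
        assert set(local["cluster"]) == {1, 2}
        assert (local["p"] == global_["p"]).all()
        # BH monotonicity: within any scope, q ordering follows p ordering
        for df in (local, global_):
            s = df.sort_values("p")
            assert s["q"].is_monotonic_increasing or np.allclose(
                np.diff(s["q"]), np.clip(np.diff(s["q"]), 0, None), atol=1e-12)


def test_math_oracle_for_hypergeom_tail():
    """scipy tail sum equals the exact combinatorial enumeration."""
    from scipy.stats import hypergeom

    n_ref, big_k, n = 20, 7, 6
    for k in range(0, min(big_k, n) + 1):
        exact = sum(
            math.comb(big_k, j) * math.comb(n_ref - big_k, n - j)
            for j in range(k, min(big_k, n) + 1)
        ) / math.comb(n_ref, n)
        assert hypergeom.sf(k - 1, n_ref, big_k, n) == pytest.approx(exact, abs=1e-12)
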