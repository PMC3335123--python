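"""Consensus across study-specific networks.

The consensus ("conserved") network keeps the links that recur in every
study network; its node set is the endpoints of surviving links, since an
isolated shared label carries no co-expression evidence.  Companions:
pairwise overlap accounting, a degree-profile PCA that places whole
networks in a common connectivity space, best-match cluster overlap
between two partitions, and mapping of a gene set into a reference
interactome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import networkx as nx
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from coexnet.modules import Partition

logger = logging.getLogger(__name__)


@dataclass
class OverlapReport:
    """Shared gene / link counts per network pair and for all networks."""

    names: list[str]
    pairwise: dict[tuple[int, int], tuple[int, int]]  # (i,j) -> (genes, links)
    all_genes: int
    all_links: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"network_a": self.names[i], "network_b": self.names[j],
             "shared_genes": g, "shared_links": l}
            for (i, j), (g, l) in sorted(self.pairwise.items())
        ]
        rows.append({"network_a": "ALL", "network_b": "ALL",
                     "shared_genes": self.all_genes, "shared_links": self.all_links})
        return pd.DataFrame(rows)


@dataclass
class PCAProjection:
    """Per-network coordinates on the first two principal components."""

    names: list[str]
    coordinates: np.ndarray  # (n_networks, 2)
    explained_variance: np.ndarray  # fractions, length 2


def _edge_set(net: nx.Graph) -> set[frozenset]:
    return {frozenset((a, b)) for a, b in net.edges()}


def intersect_networks(nets: list[nx.Graph], warn_empty: bool = True) -> nx.Graph:
    """Links present in every network; nodes are their endpoints."""
    if len(nets) < 2:
        raise ValueError("need >= 2 networks")
    shared = _edge_set(nets[0])
    for net in nets[1:]:
        shared &= _edge_set(net)
    g = nx.Graph(name="consensus")
    for e in shared:
        a, b = tuple(e)
        g.add_edge(a, b)
    if not shared and warn_empty:
        logger.warning("network intersection is empty")
    return g


def pairwise_overlap(nets: list[nx.Graph], names: list[str] | None = None) -> OverlapReport:
    """Shared node-label and link counts for every pair plus the all-way consensus."""
    if len(nets) < 2:
        raise ValueError("need >= 2 networks")
    if names is None:
        names = [net.graph.get("name") or f"net{i + 1}" for i, net in enumerate(nets)]
    edge_sets = [_edge_set(n) for n in nets]
    node_sets = [set(n.nodes()) for n in nets]
    pairwise = {}
    for i in range(len(nets)):
        for j in range(i + 1, len(nets)):
            pairwise[(i, j)] = (len(node_sets[i] & node_sets[j]),
                                len(edge_sets[i] & edge_sets[j]))
    inter = intersect_networks(nets, warn_empty=False)
    return OverlapReport(names=names, pairwise=pairwise,
                         all_genes=inter.number_of_nodes(),
                         all_links=inter.number_of_edges())


def degree_profile_pca(nets: list[nx.Graph], names: list[str] | None = None) -> PCAProjection:
    """Project networks onto principal components of their common-gene degrees.

    The networks x common-genes degree matrix is column (gene) centered —
    no variance scaling, so connectivity magnitude stays in the signal —
    and decomposed by SVD.  Signs are fixed by making the largest-magnitude
    gene loading of each axis positive, so the projection is deterministic.
    """
    if len(nets) < 3:
        raise ValueError("need >= 3 networks for a meaningful projection")
    common = set(nets[0].nodes())
    for net in nets[1:]:
        common &= set(net.nodes())
    common = sorted(common)
    if len(common) < 2:
        raise ValueError(f"need >= 2 common genes, got {len(common)}")
    if names is None:
        names = [net.graph.get("name") or f"net{i + 1}" for i, net in enumerate(nets)]
    x = np.array([[net.degree(g) for g in common] for net in nets], dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for k in range(min(2, vt.shape[0])):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    coords = u[:, :2] * s[:2]
    if coords.shape[1] < 2:  # fewer than 2 non-trivial axes
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    total = float(np.sum(s**2))
    explained = (s[:2] ** 2 / total) if total > 0 else np.zeros(2)
    if len(explained) < 2:
        explained = np.pad(explained, (0, 2 - len(explained)))
    return PCAProjection(names=names, coordinates=coords, explained_variance=explained)


def partition_overlap_jaccard(p1: "Partition", p2: "Partition",
                              min_size: int = 10) -> pd.DataFrame:
    """Best-match Jaccard overlap of p1 clusters against p2 clusters.

    Only p1 clusters with more than ``min_size`` genes are scored; each is
    matched to the p2 cluster maximizing |A∩B| / |A∪B|.
    """
    c2 = p2.clusters()
    rows = []
    for cid, members in sorted(p1.clusters().items(), key=lambda kv: str(kv[0])):
        if len(members) <= min_size:
            continue
        best_j, best_id = 0.0, None
        for cid2, members2 in c2.items():
            inter = len(members & members2)
            if inter == 0:
                continue
            j = inter / len(members | members2)
            if j > best_j:
                best_j, best_id = j, cid2
        rows.append({"cluster": cid, "size": len(members),
                     "best_match": best_id, "jaccard": best_j})
    return pd.DataFrame(rows, columns=["cluster", "size", "best_match", "jaccard"])


def map_gene_set(reference: nx.Graph, genes) -> tuple[frozenset, nx.Graph, float]:
    """Place a gene set in a reference interactome.

    Returns the mapped genes (those present among reference nodes), the
    subnetwork of reference edges with both endpoints mapped, and the
    mapped fraction.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("empty gene set")
    mapped = frozenset(genes & set(reference.nodes()))
    sub = nx.Graph(reference.subgraph(mapped))
    return mapped, sub, len(mapped) / len(genes)
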