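"""Randomization null models.

Degree-preserving Maslov-Sneppen edge rewiring, the randomized-intersection
null for multi-network consensus significance, and size-matched random
partitions for functional-coherence baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import networkx as nx
import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from coexnet.modules import Partition


@dataclass
class NullDistribution:
    """Samples of a statistic under a randomization null."""

    statistic: str
    samples: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if len(self.samples) > 1 else 0.0

    @property
    def n_reps(self) -> int:
        return len(self.samples)


def maslov_sneppen(
    net: nx.Graph,
    n_swaps: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> nx.Graph:
    """Degree-preserving edge rewiring (Maslov-Sneppen model).

    Each attempt picks two distinct edges (a,b), (c,d) and proposes the
    swap to (a,d), (c,b); proposals that would create a self-loop or a
    multi-edge are rejected but still count toward ``n_swaps`` (attempt
    counting).  The default number of attempts is 4x|E|.  The output is
    always a simple graph with exactly the input degree sequence; a graph
    admitting no valid swap (e.g. a triangle) comes back as a copy flagged
    ``ms_saturated``.
    """
    if net.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to rewire")
    if rng is None:
        rng = np.random.default_rng(seed)
    g = net.copy()
    if n_swaps is None:
        n_swaps = 4 * g.number_of_edges()
    edges = list(g.edges())
    n_edges = len(edges)
    applied = 0
    for _ in range(n_swaps):
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):
            a, b = b, a
        if rng.integers(0, 2):
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        if {a, d} == {c, b}:
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        applied += 1
    g.graph["ms_swap_attempts"] = n_swaps
    g.graph["ms_swaps_applied"] = applied
    g.graph["ms_saturated"] = applied == 0
    return g


def zscore(observed: float, null: NullDistribution) -> float:
    """Standard score of an observation against a null distribution."""
    if null.sd == 0:
        raise ValueError("null distribution has zero spread")
    return (observed - null.mean) / null.sd


def intersection_null(
    nets: list[nx.Graph],
    n_reps: int = 200,
    seed: int = 0,
    n_swaps: int | None = None,
) -> tuple[NullDistribution, NullDistribution]:
    """Null distribution of consensus size under independent rewiring.

    Every repetition rewires each input network independently (4x|E| swap
    attempts unless overridden) and records the shared-link count of the
    all-way intersection together with its gene count (distinct endpoints
    of the surviving shared links).  Each (network, repetition) pair uses
    its own RNG substream, so results are reproducible and order-stable.
    """
    from coexnet.consensus import intersect_networks

    if len(nets) < 2:
        raise ValueError("need >= 2 networks")
    genes = np.empty(n_reps)
    links = np.empty(n_reps)
    for rep in range(n_reps):
        if n_swaps == 0:
            rewired = nets
        else:
            rewired = [
                maslov_sneppen(net, n_swaps=n_swaps,
                               rng=np.random.default_rng([seed, idx, rep]))
                for idx, net in enumerate(nets)
            ]
        inter = intersect_networks(rewired, warn_empty=False)
        genes[rep] = inter.number_of_nodes()
        links[rep] = inter.number_of_edges()
    return (NullDistribution("genes", genes), NullDistribution("links", links))


def random_partition(p: "Partition", seed: int | None = None,
                     rng: np.random.Generator | None = None) -> "Partition":
    """Size-matched random partition: permute gene labels across cluster slots.

    The multiset of cluster sizes is preserved exactly; only which gene
    occupies which slot is randomized (uniformly over permutations).  The
    stored modularity is dropped since it no longer describes the shuffled
    assignment.
    """
    from coexnet.modules import Partition

    if rng is None:
        rng = np.random.default_rng(seed)
    genes = list(p.assignment)
    labels = [p.assignment[g] for g in genes]
    perm = rng.permutation(len(genes))
    new_assignment = {genes[perm[i]]: labels[i] for i in range(len(genes))}
    return Partition(assignment=new_assignment, modularity=None)
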