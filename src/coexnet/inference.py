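"""Relevance-network inference from expression matrices.

A co-expression network links gene pairs whose Pearson correlation exceeds
a threshold.  The threshold itself is chosen by a topology-driven scan: for
each candidate threshold the average clustering coefficient of the real
network is compared with the mean over degree-preserving Maslov-Sneppen
rewirings, and the first local maximum of the real-minus-random difference
over the grid 0.50 <= PCC <= 1.0 is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from coexnet.io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene Pearson correlation matrix."""

    gene_ids: list[str]
    matrix: np.ndarray
    n_samples: int
    excluded_constant: list[str] = field(default_factory=list)


@dataclass
class ThresholdScan:
    """Per-threshold clustering coefficients of real vs rewired networks.

    ``diff = c_real - c_rand``; grid points whose network had fewer than 3
    edges record a difference of 0 and are flagged in ``too_small``.
    """

    grid: np.ndarray
    c_real: np.ndarray
    c_rand: np.ndarray
    diff: np.ndarray
    too_small: np.ndarray
    n_rewires: int
    selected_threshold: float | None = None
    fallback: bool = False


def correlation_matrix(m: ExpressionMatrix) -> CorrelationMatrix:
    """Pairwise product-moment correlations of gene expression vectors.

    Genes with constant expression (undefined correlations) are excluded
    and reported on the result; fewer than 3 samples is an error.
    """
    if m.n_samples < 3:
        raise ValueError(f"need >= 3 samples for correlations, got {m.n_samples}")
    arr = m.values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    keep = sd > 0
    excluded = [g for g, k in zip(m.gene_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all genes have constant expression")
    if excluded:
        logger.info("excluding %d constant gene(s): %s", len(excluded), excluded[:10])
    arr = arr[keep]
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    r = np.corrcoef(arr)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(gene_ids=genes, matrix=r, n_samples=m.n_samples,
                             excluded_constant=excluded)


def pcc_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation under the null rho = 0.

    Uses t = r sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom; |r| = 1
    is the boundary case and returns exactly 0.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def build_network(c: CorrelationMatrix, tau: float, mode: str = "signed") -> nx.Graph:
    """Threshold a correlation matrix into an undirected unweighted network.

    ``signed`` links pairs with r >= tau (the default reading of
    "correlated above a threshold"); ``absolute`` uses |r| >= tau.  Genes
    with no suprathreshold partner do not appear in the node set.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    r = c.matrix if mode == "signed" else np.abs(c.matrix)
    iu, ju = np.triu_indices(len(c.gene_ids), k=1)
    mask = r[iu, ju] >= tau
    g = nx.Graph()
    genes = c.gene_ids
    g.add_edges_from((genes[i], genes[j]) for i, j in zip(iu[mask], ju[mask]))
    return g


def _avg_clustering(g: nx.Graph) -> float:
    # mean local clustering over the network's nodes; degree-<2 nodes count 0
    return nx.average_clustering(g, count_zeros=True) if g.number_of_nodes() else 0.0


def threshold_scan(
    m: ExpressionMatrix,
    grid_start: float = 0.50,
    grid_stop: float = 1.0,
    grid_step: float = 0.01,
    n_rewires: int = 10,
    seed: int = 0,
    mode: str = "signed",
) -> ThresholdScan:
    """Scan correlation thresholds, comparing real vs rewired clustering.

    At each grid point the network is built, its average clustering
    coefficient recorded, and ``n_rewires`` Maslov-Sneppen randomizations
    (4x|E| swap attempts each) supply the degree-matched random reference.
    """
    from coexnet.nulls import maslov_sneppen

    if grid_start < 0.50 - 1e-12 or grid_stop > 1.0 + 1e-12:
        raise ValueError("grid must lie within [0.50, 1.0]")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n_pts = int(round((grid_stop - grid_start) / grid_step)) + 1
    grid = np.round(grid_start + grid_step * np.arange(n_pts), 10)
    grid = grid[(grid >= grid_start - 1e-12) & (grid <= grid_stop + 1e-12)]

    corr = correlation_matrix(m)
    c_real = np.zeros(len(grid))
    c_rand = np.zeros(len(grid))
    too_small = np.zeros(len(grid), dtype=bool)
    any_edges = False
    for k, tau in enumerate(grid):
        g = build_network(corr, float(tau), mode=mode)
        n_edges = g.number_of_edges()
        if n_edges > 0:
            any_edges = True
        if n_edges < 3:
            too_small[k] = True
            continue
        c_real[k] = _avg_clustering(g)
        reps = []
        for rep in range(n_rewires):
            rng = np.random.default_rng([seed, k, rep])
            reps.append(_avg_clustering(maslov_sneppen(g, rng=rng)))
        c_rand[k] = float(np.mean(reps))
    if not any_edges:
        raise ValueError("no edges at any grid threshold; data uncorrelated or grid too high")
    diff = c_real - c_rand
    diff[too_small] = 0.0
    return ThresholdScan(grid=grid, c_real=c_real, c_rand=c_rand, diff=diff,
                         too_small=too_small, n_rewires=n_rewires)


def select_threshold(scan: ThresholdScan) -> float:
    """First local maximum of the real-minus-random clustering difference.

    Returns the smallest grid point t_k with diff(t_{k-1}) < diff(t_k) >=
    diff(t_{k+1}) (grid endpoints are ineligible).  Without an interior
    local maximum the argmax of the difference is returned and the scan is
    flagged ``fallback``.  A completely flat difference is an error.
    """
    d = scan.diff
    if len(d) < 3:
        raise ValueError("scan too short to select a threshold")
    if np.allclose(d, d[0]):
        raise ValueError("flat clustering-coefficient difference; cannot select a threshold")
    for k in range(1, len(d) - 1):
        if d[k - 1] < d[k] >= d[k + 1]:
            scan.selected_threshold = float(scan.grid[k])
            scan.fallback = False
            return scan.selected_threshold
    k = int(np.argmax(d))
    scan.selected_threshold = float(scan.grid[k])
    scan.fallback = True
    logger.warning("no interior local maximum; falling back to argmax at %.3f",
                   scan.selected_threshold)
    return scan.selected_threshold


def scan_to_frame(scan: ThresholdScan):
    """ThresholdScan as a tidy DataFrame (for TSV export / plotting)."""
    import pandas as pd

    return pd.DataFrame({
        "threshold": scan.grid,
        "c_real": scan.c_real,
        "c_rand": scan.c_rand,
        "diff": scan.diff,
        "too_small": scan.too_small,
    })
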