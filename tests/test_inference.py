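"""Correlation, thresholded networks, and automated threshold selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from coexnet import (
    ExpressionMatrix,
    ModuleSpec,
    SyntheticConfig,
    build_network,
    correlation_matrix,
    generate_study,
    pcc_pvalue,
    select_threshold,
    threshold_scan,
)
from coexnet.inference import ThresholdScan


def make_em(rows, genes=None, samples=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=samples))


class TestCorrelationMatrix:
    @pytest.mark.parametrize("y, expected", [
        ([2, 4, 6], 1.0),     # perfect linear
        ([6, 4, 2], -1.0),    # perfect anti-linear
    ])
    def test_perfect_correlations(self, y, expected):
        c = correlation_matrix(make_em([[1, 2, 3], y]))
        assert c.matrix[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_hand_computed_product_moment(self):
        # x=(1,2,3,4), y=(1,3,2,4): cov sum 4, each centered SS 5 -> r = 0.8
        c = correlation_matrix(make_em([[1, 2, 3, 4], [1, 3, 2, 4]]))
        assert c.matrix[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_constant_gene_excluded_and_reported(self):
        c = correlation_matrix(make_em([[1, 2, 3], [5, 5, 5], [3, 2, 1]]))
        assert c.excluded_constant == ["g1"]
        assert c.gene_ids == ["g0", "g2"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(make_em([[1, 2], [2, 1]]))

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_matrix(make_em([[1, 1, 1], [2, 2, 2]]))

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 20))
        c1 = correlation_matrix(make_em(x))
        c2 = correlation_matrix(make_em(3.7 * x + 11.0))
        assert np.allclose(c1.matrix, c2.matrix, atol=1e-10)


class TestPccPvalue:
    def test_zero_correlation_gives_p_one(self):
        for n in (3, 10, 100):
            assert pcc_pvalue(0.0, n) == pytest.approx(1.0)

    def test_boundary_correlation_gives_p_zero(self):
        assert pcc_pvalue(1.0, 5) == 0.0
        assert pcc_pvalue(-1.0, 5) == 0.0

    def test_matches_quadrature_of_t_density(self):
        # independent oracle: integrate the t density directly
        r, n = 0.5, 12
        df = n - 2
        t_obs = r * math.sqrt(df) / math.sqrt(1 - r * r)

        def t_pdf(t):
            c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            return c * (1 + t * t / df) ** (-(df + 1) / 2)

        tail, _ = quad(t_pdf, t_obs, np.inf)
        assert pcc_pvalue(r, n) == pytest.approx(2 * tail, abs=1e-6)


class TestBuildNetwork:
    def test_single_perfect_pair_at_tau_one(self):
        c = correlation_matrix(make_em([[1, 2, 3], [2, 4, 6], [1, 0, 1]]))
        g = build_network(c, 1.0)
        assert set(map(frozenset, g.edges())) == {frozenset(("g0", "g1"))}
        assert "g2" not in g  # isolated genes excluded

    def test_edges_match_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        m = make_em(rng.standard_normal((4, 30)))
        c = correlation_matrix(m)
        tau = 0.2
        expected = set()
        for i in range(4):
            for j in range(i + 1, 4):
                if c.matrix[i, j] >= tau:
                    expected.add(frozenset((f"g{i}", f"g{j}")))
        g = build_network(c, tau)
        assert set(map(frozenset, g.edges())) == expected

    def test_absolute_mode_keeps_negative_correlations(self):
        c = correlation_matrix(make_em([[1, 2, 3], [6, 4, 2]]))
        assert build_network(c, 0.9, mode="signed").number_of_edges() == 0
        assert build_network(c, 0.9, mode="absolute").number_of_edges() == 1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        c = correlation_matrix(make_em(rng.standard_normal((12, 15))))
        edges = {}
        for tau in (0.1, 0.3, 0.5, 0.7, 0.9):
            edges[tau] = set(map(frozenset, build_network(c, tau).edges()))
        taus = sorted(edges)
        for lo, hi in zip(taus, taus[1:]):
            assert edges[hi] <= edges[lo]


class TestThresholdScan:
    def test_planted_modules_elevate_real_clustering(self):
        # two modules: rewiring mixes them and destroys planted triangles
        # (a single module is a clique, which rewiring cannot change)
        cfg = SyntheticConfig(n_genes=20, n_samples_per_study=80,
                              shared_modules=(ModuleSpec(10, 0.85), ModuleSpec(8, 0.85)),
                              private_modules_per_study=(), seed=3)
        m = generate_study(cfg, 0)
        scan = threshold_scan(m, grid_step=0.05, n_rewires=5, seed=1)
        below = scan.grid < 0.85
        usable = below & ~scan.too_small
        assert usable.any()
        assert scan.diff[usable].max() > 0

    def test_pure_noise_diff_near_zero(self):
        diffs = []
        for seed in range(10):
            cfg = SyntheticConfig(n_genes=20, n_samples_per_study=50,
                                  shared_modules=(), private_modules_per_study=(),
                                  seed=seed)
            m = generate_study(cfg, 0)
            try:
                scan = threshold_scan(m, grid_step=0.05, n_rewires=5, seed=seed)
            except ValueError:  # no edges anywhere on the grid: diff is all 0
                diffs.append(0.0)
                continue
            diffs.append(float(np.mean(np.abs(scan.diff))))
        assert np.mean(diffs) < 0.05

    def test_grid_bounds_honored(self, three_studies):
        m = three_studies[0][0]
        scan = threshold_scan(m, grid_step=0.1, n_rewires=2, seed=0)
        assert scan.grid[0] >= 0.50 and scan.grid[-1] <= 1.0
        with pytest.raises(ValueError, match="grid"):
            threshold_scan(m, grid_start=0.3)


class TestSelectThreshold:
    @staticmethod
    def make_scan(grid, diff):
        grid = np.asarray(grid, dtype=float)
        diff = np.asarray(diff, dtype=float)
        return ThresholdScan(grid=grid, c_real=diff, c_rand=np.zeros_like(diff),
                             diff=diff, too_small=np.zeros(len(diff), dtype=bool),
                             n_rewires=1)

    def test_first_local_maximum_by_enumeration(self):
        scan = self.make_scan([0.5, 0.6, 0.7, 0.8, 0.9],
                              [0.10, 0.20, 0.15, 0.30, 0.05])
        assert select_threshold(scan) == pytest.approx(0.6)
        assert not scan.fallback

    def test_strictly_increasing_falls_back_to_last_point(self):
        scan = self.make_scan([0.5, 0.6, 0.7, 0.8], [0.1, 0.2, 0.3, 0.4])
        assert select_threshold(scan) == pytest.approx(0.8)
        assert scan.fallback

    def test_single_interior_peak(self):
        scan = self.make_scan([0.5, 0.6, 0.7], [0.1, 0.5, 0.2])
        assert select_threshold(scan) == pytest.approx(0.6)

    def test_flat_difference_is_an_error(self):
        scan = self.make_scan([0.5, 0.6, 0.7], [0.2, 0.2, 0.2])
        with pytest.raises(ValueError, match="flat"):
            select_threshold(scan)
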