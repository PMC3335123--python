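"""Synthetic multi-study expression data with planted co-expression modules.

The generator emulates the statistical structure a consensus co-expression
analysis relies on: several studies measure a common gene universe; a set of
*shared* modules is co-expressed in every study, each study additionally has
*private* modules of its own, and the remaining genes are independent noise.

Module expression follows a single-factor model.  Gene *g* in module *m*
with target within-module correlation rho is generated as

    x_g = w * f_m + eps_g,   w = sigma_e * sqrt(rho / (1 - rho)),

with ``f_m`` a standard-normal latent factor shared by the module's genes
(drawn fresh per study) and ``eps_g ~ N(0, sigma_e^2)`` independent noise,
so that the population Pearson correlation of any within-module pair equals
rho exactly; only this second-moment structure matters downstream.  The
degenerate settings ``noise_sd = 0`` or ``rho = 1`` plant a rank-1 block
(all pairwise correlations exactly 1).

Each study draws from its own RNG stream derived from ``(seed,
study_index)``, so adding studies never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import zeta

from coexnet.io import AnnotationCatalog, ExpressionMatrix


@dataclass(frozen=True)
class ModuleSpec:
    """Size and target within-module Pearson correlation of one planted module."""

    size: int
    within_corr: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not (0.0 < self.within_corr <= 1.0):
            raise ValueError("within_corr must lie in (0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic multi-study generator.

    Defaults plant one shared module (20 genes, rho = 0.9) and one private
    module per study (15 genes, rho = 0.9) in a 100-gene universe measured
    over 100 samples per study across 3 studies — the regime in which a
    consensus pipeline should recover shared structure essentially
    completely while private modules cannot recur across studies.
    """

    n_studies: int = 3
    n_genes: int = 100
    n_samples_per_study: int = 100
    shared_modules: tuple[ModuleSpec, ...] = (ModuleSpec(20, 0.9),)
    private_modules_per_study: tuple[ModuleSpec, ...] = (ModuleSpec(15, 0.9),)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shared_modules", tuple(
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in self.shared_modules))
        object.__setattr__(self, "private_modules_per_study", tuple(
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in self.private_modules_per_study))
        if self.n_samples_per_study < 4:
            raise ValueError("n_samples_per_study must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        used = sum(m.size for m in self.shared_modules) + sum(
            m.size for m in self.private_modules_per_study)
        if used > self.n_genes:
            raise ValueError(
                f"module sizes ({used} genes) exceed n_genes ({self.n_genes})")


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure.

    ``modules`` maps module id to its gene set; ``shared`` flags modules
    present in every study; ``expected_edges`` holds every within-module
    gene pair of the shared modules — the edges a consensus pipeline should
    recover.  Module ids are ``s1, s2, ...`` for shared and ``p{study}.{k}``
    for study-private modules; genes are labelled ``G{module}_{index}``
    (traceable to their module) and fill-in noise genes ``N{index}``.
    """

    modules: dict[str, frozenset[str]]
    shared: dict[str, bool]
    expected_edges: frozenset[frozenset[str]]

    def private_gene_set(self) -> frozenset[str]:
        out: set[str] = set()
        for mid, genes in self.modules.items():
            if not self.shared[mid]:
                out |= genes
        return frozenset(out)

    def to_json_dict(self) -> dict:
        return {
            "modules": {mid: sorted(g) for mid, g in sorted(self.modules.items())},
            "shared": dict(sorted(self.shared.items())),
            "expected_edges": sorted(sorted(e) for e in self.expected_edges),
        }


def _module_layout(config: SyntheticConfig, study_index: int):
    """Module id -> gene labels for one study, plus the noise gene labels."""
    layout: dict[str, list[str]] = {}
    for i, spec in enumerate(config.shared_modules):
        mid = f"s{i + 1}"
        layout[mid] = [f"G{mid}_{j + 1}" for j in range(spec.size)]
    for k, spec in enumerate(config.private_modules_per_study):
        mid = f"p{study_index + 1}.{k + 1}"
        layout[mid] = [f"G{mid}_{j + 1}" for j in range(spec.size)]
    n_planted = sum(len(v) for v in layout.values())
    noise = [f"N{j + 1}" for j in range(config.n_genes - n_planted)]
    return layout, noise


def _module_specs(config: SyntheticConfig, study_index: int) -> dict[str, ModuleSpec]:
    specs: dict[str, ModuleSpec] = {}
    for i, spec in enumerate(config.shared_modules):
        specs[f"s{i + 1}"] = spec
    for k, spec in enumerate(config.private_modules_per_study):
        specs[f"p{study_index + 1}.{k + 1}"] = spec
    return specs


def generate_study(config: SyntheticConfig, study_index: int) -> ExpressionMatrix:
    """Generate the expression matrix of one study under the factor model.

    Deterministic for a fixed ``(config.seed, study_index)`` pair.
    """
    if not (0 <= study_index):
        raise ValueError("study_index must be >= 0")
    rng = np.random.default_rng([config.seed, study_index])
    n = config.n_samples_per_study
    layout, noise_genes = _module_layout(config, study_index)
    specs = _module_specs(config, study_index)

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    for mid, genes in layout.items():
        spec = specs[mid]
        f = rng.standard_normal(n)
        rho = spec.within_corr
        if config.noise_sd == 0.0 or rho == 1.0:
            # degenerate rank-1 block: every gene is the factor itself
            block = np.tile(f, (len(genes), 1))
        else:
            w = config.noise_sd * np.sqrt(rho / (1.0 - rho))
            eps = rng.standard_normal((len(genes), n)) * config.noise_sd
            block = w * f + eps
        gene_ids.extend(genes)
        rows.append(block)
    if noise_genes:
        sd = config.noise_sd if config.noise_sd > 0 else 1.0
        rows.append(rng.standard_normal((len(noise_genes), n)) * sd)
        gene_ids.extend(noise_genes)
    values = pd.DataFrame(
        np.vstack(rows), index=gene_ids,
        columns=[f"S{j + 1}" for j in range(n)], dtype=float,
    )
    return ExpressionMatrix(values, study_name=f"study{study_index + 1}")


def generate_multi_study(config: SyntheticConfig) -> tuple[list[ExpressionMatrix], PlantedTruth]:
    """Generate all studies of the design plus the planted ground truth.

    Shared modules reuse the same gene labels in every study; private
    modules carry study-specific labels and can never recur across studies.
    """
    if config.n_studies < 2:
        raise ValueError("n_studies must be >= 2")
    studies = [generate_study(config, i) for i in range(config.n_studies)]

    modules: dict[str, frozenset[str]] = {}
    shared: dict[str, bool] = {}
    for i in range(config.n_studies):
        layout, _ = _module_layout(config, i)
        for mid, genes in layout.items():
            modules[mid] = frozenset(genes)
            shared[mid] = mid.startswith("s")
    expected: set[frozenset[str]] = set()
    for mid, genes in modules.items():
        if shared[mid]:
            gl = sorted(genes)
            for a_i in range(len(gl)):
                for b_i in range(a_i + 1, len(gl)):
                    expected.add(frozenset((gl[a_i], gl[b_i])))
    truth = PlantedTruth(modules=modules, shared=shared, expected_edges=frozenset(expected))
    return studies, truth


def generate_annotations(
    truth: PlantedTruth,
    n_noise_terms: int,
    seed: int,
    universe: frozenset[str] | None = None,
) -> AnnotationCatalog:
    """Annotation catalog matched to a planted truth.

    One term per planted module (its exact gene set) plus ``n_noise_terms``
    random gene sets with sizes drawn uniformly in [5, 50] from ``universe``
    (default: all planted genes), emulating uninformative annotation terms.
    """
    if not truth.modules:
        raise ValueError("empty truth")
    rng = np.random.default_rng(seed)
    pool = sorted(universe) if universe is not None else sorted(
        g for genes in truth.modules.values() for g in genes)
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for mid, genes in sorted(truth.modules.items()):
        tid = f"T_{mid}"
        terms[tid] = frozenset(genes)
        names[tid] = f"planted module {mid}"
    for j in range(n_noise_terms):
        size = int(rng.integers(5, 51))
        size = min(size, len(pool))
        genes = frozenset(rng.choice(pool, size=size, replace=False).tolist())
        tid = f"R{j + 1}"
        terms[tid] = genes
        names[tid] = f"random term {j + 1}"
    return AnnotationCatalog(terms=terms, names=names, namespace="synthetic")


def sample_powerlaw_degrees(alpha: float, xmin: int, n: int, seed: int) -> np.ndarray:
    """Sample n integers from the discrete power law p(x) ∝ x^-alpha, x >= xmin.

    Exact inverse-CDF sampling on the Hurwitz-zeta-normalised mass function:
    the survival function is S(x) = zeta(alpha, x) / zeta(alpha, xmin) and a
    uniform draw u maps to the unique x with S(x+1) <= u < S(x).
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1 (the law is non-normalizable otherwise)")
    if xmin < 1:
        raise ValueError("xmin must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    norm = zeta(alpha, xmin)
    # survival grid S(xmin..xmax), grown until it covers the smallest draw
    # (capped; draws deeper in the tail fall back to per-sample bisection)
    width = 1024
    while True:
        xs = np.arange(xmin, xmin + width + 1)
        surv = zeta(alpha, xs) / norm
        if surv[-1] <= u.min() or width >= 1 << 22:
            break
        width *= 4
    # number of grid points with S > u gives the sample offset from xmin
    counts = np.searchsorted(-surv, -u, side="right")
    out = (xmin + counts - 1).astype(np.int64)
    deep = u < surv[-1]
    if deep.any():
        for i in np.flatnonzero(deep):
            lo = int(xs[-1])  # S(lo) > u
            hi = lo * 2
            while zeta(alpha, hi) / norm > u[i]:
                lo, hi = hi, hi * 2
            while hi - lo > 1:  # S(lo) > u >= S(hi)
                mid = (lo + hi) // 2
                if zeta(alpha, mid) / norm > u[i]:
                    lo = mid
                else:
                    hi = mid
            out[i] = lo
    return out


def write_truth_json(truth: PlantedTruth, path: str | Path) -> None:
    import json

    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1))
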