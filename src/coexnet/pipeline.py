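"""Configuration-driven orchestration of the full consensus analysis.

One call runs: obtain expression matrices (synthetic design or TSV files)
-> per-study threshold scan and network inference -> consensus intersection
and pairwise overlap -> randomized-intersection significance -> global
topology metrics and a degree-distribution power-law fit -> module
detection -> functional coherence against random partitions -> per-cluster
enrichment -> a machine-readable JSON manifest recording every parameter,
seed, and headline number.  Fixed seeds make re-runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from coexnet import consensus as cns
from coexnet import inference, modules, nulls, synthetic, topology
from coexnet.io import (
    ExpressionMatrix,
    read_expression_table,
    read_gmt,
    write_edge_list,
    write_expression_table,
    write_gmt,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Either ``synthetic`` (a :class:`~coexnet.synthetic.SyntheticConfig`) or
    ``expression_paths`` must be given.  ``drop_sample_prefix`` removes
    samples whose id starts with the prefix before inference (e.g. to
    re-run on tumor-only samples); ``fixed_threshold`` skips the scan and
    thresholds every study at the given PCC.
    """

    synthetic: synthetic.SyntheticConfig | None = None
    expression_paths: list[str] = field(default_factory=list)
    drop_sample_prefix: str | None = None
    grid_start: float = 0.50
    grid_stop: float = 1.0
    grid_step: float = 0.01
    n_rewires: int = 10
    mode: str = "signed"
    fixed_threshold: float | None = None
    n_reps: int = 200
    n_boot: int = 1000
    clustering_method: str = "louvain"
    mcl_inflation: float = 2.0
    n_random_partitions: int = 100
    n_noise_terms: int = 20
    gmt_path: str | None = None
    term_min_size: int = 5
    term_max_size: int = 50
    enrich_min_cluster_size: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("shared_modules", "private_modules_per_study"):
                if key in syn:
                    syn[key] = tuple(synthetic.ModuleSpec(*m) for m in syn[key])
            raw["synthetic"] = synthetic.SyntheticConfig(**syn)
        return cls(**raw)

    def to_manifest_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


def _load_matrices(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        studies, truth = synthetic.generate_multi_study(cfg.synthetic)
        return studies, truth
    if not cfg.expression_paths:
        raise ValueError("config needs either a synthetic design or expression_paths")
    return [read_expression_table(p) for p in cfg.expression_paths], None


def _filter_samples(m: ExpressionMatrix, prefix: str) -> ExpressionMatrix:
    keep = [s for s in m.sample_ids if not s.startswith(prefix)]
    if len(keep) < 4:
        raise ValueError(f"{m.study_name}: fewer than 4 samples left after dropping {prefix!r}*")
    return ExpressionMatrix(m.values[keep], study_name=m.study_name)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full analysis; returns the manifest (also written to disk).

    Every stage logs its elapsed time; any stage failure propagates with a
    stage-tagged error while earlier outputs remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_manifest_dict(), "stages": {}}
    stage = "setup"
    try:
        # ---- data ---------------------------------------------------------
        stage = "data"
        t0 = time.perf_counter()
        studies, truth = _load_matrices(cfg)
        if cfg.drop_sample_prefix:
            studies = [_filter_samples(m, cfg.drop_sample_prefix) for m in studies]
        for m in studies:
            write_expression_table(m, out / f"expr_{m.study_name}.tsv")
        if truth is not None:
            synthetic.write_truth_json(truth, out / "truth.json")
        manifest["stages"]["data"] = {
            "studies": [m.study_name for m in studies],
            "n_genes": [m.n_genes for m in studies],
            "n_samples": [m.n_samples for m in studies],
        }
        logger.info("stage=data seed=%d elapsed=%.2fs", cfg.seed, time.perf_counter() - t0)

        # ---- per-study inference -----------------------------------------
        stage = "inference"
        t0 = time.perf_counter()
        nets = []
        infer_info = []
        for i, m in enumerate(studies):
            corr = inference.correlation_matrix(m)
            if cfg.fixed_threshold is not None:
                tau, fallback = cfg.fixed_threshold, None
            else:
                scan = inference.threshold_scan(
                    m, cfg.grid_start, cfg.grid_stop, cfg.grid_step,
                    n_rewires=cfg.n_rewires, seed=cfg.seed + i, mode=cfg.mode)
                tau = inference.select_threshold(scan)
                fallback = scan.fallback
                inference.scan_to_frame(scan).to_csv(
                    out / f"scan_{m.study_name}.tsv", sep="\t", index=False)
            net = inference.build_network(corr, tau, mode=cfg.mode)
            net.graph["name"] = m.study_name
            write_edge_list(net, out / f"net_{m.study_name}.edges")
            nets.append(net)
            infer_info.append({"study": m.study_name, "threshold": tau,
                               "fallback": fallback,
                               "nodes": net.number_of_nodes(),
                               "edges": net.number_of_edges()})
        manifest["stages"]["inference"] = infer_info
        logger.info("stage=inference seed=%d elapsed=%.2fs", cfg.seed, time.perf_counter() - t0)

        # ---- consensus ----------------------------------------------------
        stage = "consensus"
        t0 = time.perf_counter()
        conserved = cns.intersect_networks(nets)
        write_edge_list(conserved, out / "consensus.edges")
        overlap = cns.pairwise_overlap(nets)
        overlap.to_frame().to_csv(out / "overlap.tsv", sep="\t", index=False)
        manifest["stages"]["consensus"] = {
            "nodes": conserved.number_of_nodes(),
            "edges": conserved.number_of_edges(),
        }
        logger.info("stage=consensus elapsed=%.2fs", time.perf_counter() - t0)

        # ---- intersection null -------------------------------------------
        stage = "null"
        t0 = time.perf_counter()
        null_genes, null_links = nulls.intersection_null(
            nets, n_reps=cfg.n_reps, seed=cfg.seed)
        z_genes = (nulls.zscore(conserved.number_of_nodes(), null_genes)
                   if null_genes.sd > 0 else None)
        z_links = (nulls.zscore(conserved.number_of_edges(), null_links)
                   if null_links.sd > 0 else None)
        null_report = {
            "n_reps": cfg.n_reps,
            "genes": {"mean": null_genes.mean, "sd": null_genes.sd, "z": z_genes},
            "links": {"mean": null_links.mean, "sd": null_links.sd, "z": z_links},
        }
        (out / "null.json").write_text(json.dumps({
            **null_report,
            "samples_genes": null_genes.samples.tolist(),
            "samples_links": null_links.samples.tolist(),
        }, indent=1))
        manifest["stages"]["null"] = null_report
        logger.info("stage=null reps=%d elapsed=%.2fs", cfg.n_reps, time.perf_counter() - t0)

        # ---- topology -----------------------------------------------------
        stage = "topology"
        t0 = time.perf_counter()
        rows = []
        for net in nets + [conserved]:
            gm = topology.global_metrics(net)
            rows.append({"network": net.graph.get("name", "consensus"), **gm.as_dict()})
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "metrics.tsv", sep="\t", index=False)
        manifest["stages"]["topology"] = rows
        degrees = [d for _, d in conserved.degree()]
        try:
            fit = topology.powerlaw_fit(degrees, n_boot=cfg.n_boot, seed=cfg.seed)
            manifest["stages"]["powerlaw"] = {
                "alpha": fit.alpha, "xmin": fit.xmin, "n_tail": fit.n_tail,
                "ks_distance": fit.ks_distance, "p_value": fit.p_value,
                "n_boot": fit.n_boot,
            }
        except ValueError as err:  # degenerate degree sequence
            manifest["stages"]["powerlaw"] = {"skipped": str(err)}
        logger.info("stage=topology elapsed=%.2fs", time.perf_counter() - t0)

        # ---- modules ------------------------------------------------------
        stage = "modules"
        t0 = time.perf_counter()
        if cfg.clustering_method == "louvain":
            part = modules.louvain_partition(conserved, seed=cfg.seed)
        elif cfg.clustering_method == "mcl":
            part = modules.mcl_partition(conserved, inflation=cfg.mcl_inflation)
        else:
            raise ValueError(f"unknown clustering method {cfg.clustering_method!r}")
        part.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
        manifest["stages"]["modules"] = {
            "method": cfg.clustering_method,
            "n_clusters": part.n_clusters,
            "modularity": part.modularity,
            "largest": part.sizes[0] if part.sizes else 0,
        }
        logger.info("stage=modules elapsed=%.2fs", time.perf_counter() - t0)

        # ---- annotations / coherence / enrichment ------------------------
        stage = "function"
        t0 = time.perf_counter()
        universe = set(conserved.nodes())
        if cfg.gmt_path:
            cat = read_gmt(cfg.gmt_path)
        elif truth is not None:
            cat = synthetic.generate_annotations(
                truth, n_noise_terms=cfg.n_noise_terms, seed=cfg.seed,
                universe=frozenset(universe) if universe else None)
            write_gmt(cat, out / "annotations.gmt")
        else:
            cat = None
        if cat is not None and universe:
            filtered = modules.filter_terms(
                cat, universe, cfg.term_min_size, cfg.term_max_size)
            coh = None
            if filtered.n_terms:
                try:
                    coh = modules.coherence_vs_random(
                        conserved, part, filtered,
                        n_random=cfg.n_random_partitions, seed=cfg.seed)
                except ValueError:
                    coh = None
            manifest["stages"]["coherence"] = (
                None if coh is None else {
                    "fold": coh.fold, "p_empirical": coh.p_empirical,
                    "real_mean": coh.real_mean, "n_pairs": coh.n_pairs,
                    "n_random": cfg.n_random_partitions,
                })
            enr = modules.enrich_partition(
                part, filtered, universe,
                min_cluster_size=cfg.enrich_min_cluster_size)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {
                "n_tests": int(len(enr)),
                "n_significant_q05": int((enr["q"] < 0.05).sum()) if len(enr) else 0,
            }
        else:
            manifest["stages"]["coherence"] = None
            manifest["stages"]["enrichment"] = None
        logger.info("stage=function elapsed=%.2fs", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
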