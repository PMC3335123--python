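"""Readers and writers for the pipeline's delimited-text formats.

Expression matrices travel as TSV/CSV tables (first column gene id, header
row of sample ids), gene networks as two-column edge lists, gene-set
annotations as GMT, and probe maps as two-column tables.  All readers are
strict: malformed input raises :class:`FormatError` with enough context to
locate the offending row.  Networks are always simple undirected graphs
(self-loops dropped, reversed duplicates collapsed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class ExpressionMatrix:
    """Genes x samples table of log-scale intensities.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    study_name
        Label of the originating study (used in reports).
    has_duplicate_genes
        True when the same gene id occurs on several rows (pre-collapse).
    """

    values: pd.DataFrame
    study_name: str = ""
    has_duplicate_genes: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class AnnotationCatalog:
    """Term id -> gene-set mapping with human-readable names.

    ``namespace`` carries the annotation source label (e.g. ``GO-BP``,
    ``GO-CC``, ``pathway``); gene sets are non-empty and term ids unique by
    construction of the readers and generators.
    """

    terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    namespace: str = ""

    def __post_init__(self) -> None:
        for tid, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} has an empty gene set")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def gene_to_terms(self) -> dict[str, frozenset[str]]:
        """Invert the catalog: gene id -> set of term ids annotating it."""
        out: dict[str, set[str]] = {}
        for tid, genes in self.terms.items():
            for g in genes:
                out.setdefault(g, set()).add(tid)
        return {g: frozenset(ts) for g, ts in out.items()}


def _sniff_sep(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_expression_table(path: str | Path, study_name: str | None = None) -> ExpressionMatrix:
    """Read a delimited expression table (first column gene id, header row).

    Rows containing non-numeric or missing cells are rejected with an error
    naming the offending gene ids; duplicate sample ids are a format error.
    Duplicate gene ids are retained and flagged, pending probe collapsing.
    """
    path = Path(path)
    raw = path.read_text()
    lines = [ln for ln in raw.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty expression table")
    sep = _sniff_sep(lines[0])
    header = lines[0].split(sep)
    sample_ids = [h.strip() for h in header[1:]]
    if len(sample_ids) != len(set(sample_ids)):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample ids {dupes}")
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns")

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    bad: list[str] = []
    for ln in lines[1:]:
        parts = ln.split(sep)
        gid = parts[0].strip()
        cells = parts[1:]
        if len(cells) != len(sample_ids):
            raise FormatError(f"{path}: row {gid!r} has {len(cells)} cells, expected {len(sample_ids)}")
        try:
            vals = [float(c) for c in cells]
        except ValueError:
            bad.append(gid)
            continue
        if any(np.isnan(vals)):
            bad.append(gid)
            continue
        gene_ids.append(gid)
        rows.append(vals)
    if bad:
        raise FormatError(f"{path}: non-numeric or missing values in rows {bad}")
    if not gene_ids:
        raise FormatError(f"{path}: no data rows")
    values = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    has_dup = len(gene_ids) != len(set(gene_ids))
    return ExpressionMatrix(values, study_name=study_name or path.stem, has_duplicate_genes=has_dup)


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe -> gene table (optional header)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    for i, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.replace(",", "\t").split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{i}: expected two columns, got {len(parts)}")
        probe, gene = parts
        if i == 1 and probe.lower() in {"probe", "probe_id", "probeset"}:
            continue
        if probe in mapping and mapping[probe] != gene:
            raise FormatError(f"{path}: probe {probe!r} maps to multiple genes")
        mapping[probe] = gene
    return mapping


def collapse_probes_median(m: ExpressionMatrix, probe_map: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level by the per-sample median.

    Where several probes map to one gene the median intensity per sample is
    retained (even probe counts average the two central values).  Every row
    id of ``m`` must appear in ``probe_map``.
    """
    unmapped = [p for p in m.gene_ids if p not in probe_map]
    if unmapped:
        raise ValueError(f"unmapped probe ids: {unmapped}")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, probe in enumerate(m.gene_ids):
        gene = probe_map[probe]
        if gene not in groups:
            groups[gene] = []
            order.append(gene)
        groups[gene].append(i)
    arr = m.values.to_numpy()
    collapsed = np.vstack([np.median(arr[idx, :], axis=0) for g in order for idx in [groups[g]]])
    values = pd.DataFrame(collapsed, index=order, columns=m.sample_ids)
    return ExpressionMatrix(values, study_name=m.study_name, has_duplicate_genes=False)


_EDGE_HEADER_TOKENS = {
    "source", "target", "from", "to", "gene1", "gene2", "genea", "geneb",
    "node1", "node2",
}


def read_edge_list(path: str | Path, name: str | None = None) -> nx.Graph:
    """Read a two-column edge list into a simple undirected graph.

    Reversed duplicates collapse onto one edge; self-loops are dropped and
    counted (``G.graph['self_loops_dropped']``).  A leading header line of
    recognised column names is skipped.
    """
    path = Path(path)
    g = nx.Graph(name=name or path.stem)
    self_loops = 0
    first = True
    for i, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        parts = [p.strip() for p in parts if p.strip()]
        if len(parts) != 2:
            raise FormatError(f"{path}:{i}: expected two columns, got {len(parts)}")
        a, b = parts
        if first:
            first = False
            if a.lower() in _EDGE_HEADER_TOKENS and b.lower() in _EDGE_HEADER_TOKENS:
                continue
        if a == b:
            self_loops += 1
            continue
        g.add_edge(a, b)
    if self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, self_loops)
    g.graph["self_loops_dropped"] = self_loops
    return g


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write edges as sorted tab-separated pairs (deterministic order)."""
    edges = sorted((min(str(a), str(b)), max(str(a), str(b))) for a, b in net.edges())
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_gmt(path: str | Path, namespace: str = "") -> AnnotationCatalog:
    """Read a GMT file (term, description, genes..., tab-separated)."""
    path = Path(path)
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for i, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: GMT line needs >=3 tab-separated fields")
        tid, desc = parts[0], parts[1]
        genes = [g.strip() for g in parts[2:]]
        n_empty = sum(1 for g in genes if not g)
        if n_empty:
            logger.info("%s:%d: skipped %d empty gene field(s)", path, i, n_empty)
        gene_set = frozenset(g for g in genes if g)
        if not gene_set:
            logger.info("%s:%d: term %r has no genes, skipped", path, i, tid)
            continue
        if tid in terms:
            raise FormatError(f"{path}:{i}: duplicate term id {tid!r}")
        terms[tid] = gene_set
        names[tid] = desc
    return AnnotationCatalog(terms=terms, names=names, namespace=namespace)


def write_gmt(cat: AnnotationCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(cat.terms):
            genes = "\t".join(sorted(cat.terms[tid]))
            fh.write(f"{tid}\t{cat.names.get(tid, tid)}\t{genes}\n")
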