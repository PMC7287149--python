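"""Reading, writing and joint normalization of expression-network data.

File formats handled here: expression matrices and design tables as
tab-separated text, gene-set catalogs as GMT, gene annotations as
two-column TSV, networks as canonical edge-list TSV or GraphML.

All higher modules operate on the containers defined in this module:
:class:`ExpressionMatrix`, :class:`ExperimentDesign`, gene-set dicts and
:class:`csenet.network.AdjacencyMatrix`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("csenet")

__all__ = [
    "ExpressionMatrix",
    "ExperimentDesign",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_gene_sets",
    "write_gene_sets",
    "read_annotations",
    "write_annotations",
    "quantile_normalize",
    "write_network",
    "read_network",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of normalized (log-scale) expression values.

    Values are assumed to be already normalized and log-scaled; no
    transformation is applied silently anywhere in the package.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for axis_name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {axis_name} identifier(s): {sorted(dupes)}")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, idx])


@dataclass
class ExperimentDesign:
    """Sample → sub-experiment mapping, with optional tissue and treatment.

    A sub-experiment is a group of assays obtained under identical settings,
    i.e. a replicate group; it is the unit within which mean-centering is
    applied.
    """

    sample_to_subexp: dict[str, str]
    tissue: dict[str, str] | None = None
    treatment: dict[str, str] | None = None

    def __post_init__(self) -> None:
        sizes = self.subexperiment_sizes()
        singletons = [j for j, r in sizes.items() if r == 1]
        if singletons:
            warnings.warn(
                f"{len(singletons)} sub-experiment(s) have a single sample: "
                f"{sorted(singletons)[:5]}{'...' if len(singletons) > 5 else ''}; "
                "mean-centering will zero them out",
                UserWarning,
                stacklevel=2,
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_to_subexp)

    @property
    def n_subexperiments(self) -> int:
        return len(set(self.sample_to_subexp.values()))

    def subexperiment_sizes(self) -> dict[str, int]:
        """Replicate count r_j per sub-experiment label."""
        sizes: dict[str, int] = {}
        for sub in self.sample_to_subexp.values():
            sizes[sub] = sizes.get(sub, 0) + 1
        return sizes

    def groups(self) -> dict[str, list[str]]:
        """Sub-experiment label → ordered member sample ids."""
        grouped: dict[str, list[str]] = {}
        for sample, sub in self.sample_to_subexp.items():
            grouped.setdefault(sub, []).append(sample)
        return grouped

    def check_pairing(self, X: ExpressionMatrix) -> None:
        """Raise if the design and matrix do not cover the same samples."""
        design_samples = set(self.sample_to_subexp)
        matrix_samples = set(X.sample_ids)
        missing = matrix_samples - design_samples
        extra = design_samples - matrix_samples
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"samples missing from design: {sorted(missing)}")
            if extra:
                parts.append(f"design samples absent from matrix: {sorted(extra)}")
            raise ValueError("; ".join(parts))


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for it in items:
        if it in seen:
            dupes.add(it)
        seen.add(it)
    return dupes


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column gene ids, header sample ids).

    Errors name the offending identifier or cell; no imputation is performed.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in frame.index]
    sample_ids = [str(s) for s in frame.columns]
    for axis_name, ids in (("gene", gene_ids), ("sample", sample_ids)):
        dupes = _duplicates(ids)
        if dupes:
            raise ValueError(
                f"duplicate {axis_name} identifier(s) in {path}: {sorted(dupes)}"
            )
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                raise ValueError(
                    f"missing value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r} in {path}"
                )
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {raw!r} at gene {gene_ids[i]!r}, "
                    f"sample {sample_ids[j]!r} in {path}"
                ) from None
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(X: ExpressionMatrix, path: str | Path) -> None:
    X.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Design I/O
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> ExperimentDesign:
    """Read a sample design TSV with columns sample_id, sub_experiment
    and optional tissue, treatment columns."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sub_experiment"}
    if not required.issubset(frame.columns):
        raise ValueError(f"design file must have columns {sorted(required)}")
    samples = [str(s) for s in frame["sample_id"]]
    dupes = _duplicates(samples)
    if dupes:
        raise ValueError(f"sample(s) listed twice in design: {sorted(dupes)}")
    design = ExperimentDesign(
        sample_to_subexp=dict(zip(samples, frame["sub_experiment"].astype(str))),
        tissue=dict(zip(samples, frame["tissue"].astype(str))) if "tissue" in frame else None,
        treatment=dict(zip(samples, frame["treatment"].astype(str))) if "treatment" in frame else None,
    )
    sizes = design.subexperiment_sizes()
    logger.info(
        "design: %d samples, s=%d sub-experiments, replicate counts %s",
        len(samples), design.n_subexperiments, sorted(sizes.values()),
    )
    return design


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    frame = pd.DataFrame({"sample_id": design.sample_ids})
    frame["sub_experiment"] = [design.sample_to_subexp[s] for s in frame["sample_id"]]
    if design.tissue is not None:
        frame["tissue"] = [design.tissue.get(s, "") for s in frame["sample_id"]]
    if design.treatment is not None:
        frame["treatment"] = [design.treatment.get(s, "") for s in frame["sample_id"]]
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT) and annotations
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line — name, description, members."""
    catalog: dict[str, set[str]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {line_no}: expected name, description, members")
            name = fields[0]
            if name in catalog:
                raise ValueError(f"duplicate gene-set name {name!r} at line {line_no}")
            catalog[name] = {g for g in fields[2:] if g}
    return catalog


def write_gene_sets(catalog: Mapping[str, set[str]], path: str | Path,
                    descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as handle:
        for name, members in catalog.items():
            desc = (descriptions or {}).get(name, "na")
            handle.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_annotations(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping each gene to one functional category."""
    frame = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["gene", "category"])
    genes = [str(g) for g in frame["gene"]]
    dupes = _duplicates(genes)
    if dupes:
        raise ValueError(f"gene(s) annotated twice: {sorted(dupes)}")
    return dict(zip(genes, frame["category"].astype(str)))


def write_annotations(annotations: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gene, category in annotations.items():
            handle.write(f"{gene}\t{category}\n")


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all samples of a joint matrix together.

    Every column is mapped onto the common reference distribution given by
    the across-sample mean of order statistics, preserving per-column ranks.
    Ties within a column all receive the mean of the reference values at
    their tied rank positions (rank-average dialect), which makes the
    transform deterministic and symmetric in the tied entries.
    """
    if X.n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    values = X.values
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(values, order, axis=0), axis=1)

    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        col_order = order[:, j]
        assigned = np.empty(n)
        assigned[col_order] = reference
        # average reference values over runs of tied input values
        sorted_vals = col[col_order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [n]))
        for a, b in zip(starts, stops):
            if b - a > 1:
                assigned[col_order[a:b]] = reference[a:b].mean()
        out[:, j] = assigned
    return ExpressionMatrix(X.gene_ids, X.sample_ids, out)


# ---------------------------------------------------------------------------
# Network I/O
# ---------------------------------------------------------------------------

def write_network(A, S=None, path: str | Path = "network.tsv",
                  fmt: str = "edgelist",
                  node_attributes: Mapping[str, Mapping[str, object]] | None = None) -> None:
    """Write an adjacency matrix as a canonical edge-list TSV or GraphML.

    Edge rows are unordered pairs canonicalized with the lexicographically
    smaller gene first, sorted, with the score column taken from ``S`` when
    given (blank otherwise) — diff-stable output.  GraphML nodes can carry
    extra attributes (community labels, dominance classes, ...) via
    ``node_attributes``: attribute name → {gene: value}.
    """
    if S is not None and list(S.gene_ids) != list(A.gene_ids):
        raise ValueError("score matrix gene order does not match adjacency")
    rows = []
    genes = A.gene_ids
    for i, j in zip(*np.nonzero(np.triu(A.matrix, k=1))):
        a, b = sorted((genes[i], genes[j]))
        score = "" if S is None else repr(float(S.scores[i, j]))
        rows.append((a, b, score))
    rows.sort()
    if fmt == "edgelist":
        with open(path, "w") as handle:
            handle.write("gene_a\tgene_b\tscore\n")
            for a, b, score in rows:
                handle.write(f"{a}\t{b}\t{score}\n")
    elif fmt == "graphml":
        graph = nx.Graph()
        graph.add_nodes_from(genes)
        for a, b, score in rows:
            if score:
                graph.add_edge(a, b, score=float(score))
            else:
                graph.add_edge(a, b)
        for attr_name, mapping in (node_attributes or {}).items():
            nx.set_node_attributes(graph, dict(mapping), attr_name)
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, gene_ids: Sequence[str] | None = None):
    """Read an edge-list TSV back into an adjacency matrix.

    When ``gene_ids`` is omitted the gene universe is the set of genes
    appearing in edges (sorted), so isolated nodes are not recoverable —
    pass the full universe to round-trip a network exactly.
    """
    from .network import AdjacencyMatrix

    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"}.issubset(frame.columns):
        raise ValueError(f"{path} is not an edge-list TSV (needs gene_a, gene_b)")
    if gene_ids is None:
        gene_ids = sorted(set(frame["gene_a"]) | set(frame["gene_b"]))
    index = {g: i for i, g in enumerate(gene_ids)}
    matrix = np.zeros((len(gene_ids), len(gene_ids)), dtype=np.int8)
    for a, b in zip(frame["gene_a"], frame["gene_b"]):
        if a not in index or b not in index:
            raise ValueError(f"edge gene {a if a not in index else b!r} absent from gene universe")
        matrix[index[a], index[b]] = 1
        matrix[index[b], index[a]] = 1
    return AdjacencyMatrix(list(gene_ids), matrix)
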