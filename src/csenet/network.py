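"""Binary network construction at controlled sparsity.

A score matrix is converted into a sign/adjacency matrix by retaining the
floor(ω·M) gene pairs with the largest absolute score, M = n(n−1)/2 — the
exact order-statistic equivalent of iterating a cutoff α until the fraction
of edges reaches the target sparsity ω.  Variants: a bootstrap-aggregated
network (B resamples, edges kept when their aggregated count reaches the
smallest β that keeps realized sparsity ≤ ω), a fixed-cutoff network
(|score| > cutoff), and the intersection of condition-specific networks
(an edge must appear in every input).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .correlation import ScoreMatrix, bicor_matrix, partial_matrix, pearson_matrix
from .data_io import ExpressionMatrix

logger = logging.getLogger("csenet")

__all__ = [
    "AdjacencyMatrix",
    "threshold_to_sparsity",
    "bootstrap_adjacency",
    "threshold_fixed",
    "intersect_condition_networks",
    "network_summary",
]

_METHODS = {
    "pearson": pearson_matrix,
    "partial": partial_matrix,
    "bicor": bicor_matrix,
}


@dataclass
class AdjacencyMatrix:
    """Binary, symmetric, zero-diagonal gene network.

    ``omega`` records the target sparsity when built by sparsity control;
    ``alpha`` the realized score cutoff (smallest retained |score|);
    ``beta`` the aggregated-count cutoff of the bootstrap variant;
    ``cutoff`` a fixed threshold; ``counts`` the bootstrap aggregation
    matrix (values 0..B) when applicable.
    """

    gene_ids: list[str]
    matrix: np.ndarray
    omega: float | None = None
    alpha: float | None = None
    beta: int | None = None
    cutoff: float | None = None
    counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        n = len(self.gene_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"adjacency shape {self.matrix.shape} != ({n}, {n})")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("adjacency matrix is not symmetric")
        if np.diag(self.matrix).any():
            raise ValueError("adjacency matrix has nonzero diagonal")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("adjacency matrix must be binary")
        self.matrix = self.matrix.astype(np.int8)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_possible_edges(self) -> int:
        n = self.n_genes
        return n * (n - 1) // 2

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum()) // 2

    @property
    def sparsity(self) -> float:
        return self.n_edges / self.n_possible_edges if self.n_possible_edges else 0.0

    def degrees(self) -> np.ndarray:
        return self.matrix.sum(axis=1).astype(int)

    def edge_set(self) -> set[tuple[str, str]]:
        """Edges as canonical (smaller id, larger id) pairs."""
        return {
            tuple(sorted((self.gene_ids[i], self.gene_ids[j])))
            for i, j in zip(*np.nonzero(np.triu(self.matrix, k=1)))
        }

    def has_edge(self, gene_a: str, gene_b: str) -> bool:
        i = self.gene_ids.index(gene_a)
        j = self.gene_ids.index(gene_b)
        return bool(self.matrix[i, j])


def _ranked_pairs(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by (|score| desc, i asc, j asc)."""
    iu, ju = np.triu_indices(scores.shape[0], k=1)
    magnitudes = np.abs(scores[iu, ju])
    # lexsort: last key is primary; negate for descending magnitude
    order = np.lexsort((ju, iu, -magnitudes))
    return iu[order], ju[order], magnitudes[order]


def threshold_to_sparsity(S: ScoreMatrix, omega: float) -> AdjacencyMatrix:
    """Binarize a score matrix keeping exactly floor(ω·M) top-|score| pairs.

    The realized cutoff α (the smallest retained absolute score) is stored
    on the result.  Ties at the threshold are broken deterministically by
    gene order, so the edge count is exact even for discrete scores.
    """
    if not 0.0 < omega < 1.0:
        raise ValueError("sparsity omega must lie strictly between 0 and 1")
    n = S.n_genes
    m_possible = n * (n - 1) // 2
    n_edges = int(np.floor(omega * m_possible + 1e-12))
    matrix = np.zeros((n, n), dtype=np.int8)
    if n_edges < 1:
        warnings.warn(
            f"omega*M = {omega * m_possible:.3g} < 1: resulting network is empty",
            UserWarning,
            stacklevel=2,
        )
        return AdjacencyMatrix(list(S.gene_ids), matrix, omega=omega, alpha=None)
    iu, ju, magnitudes = _ranked_pairs(S.scores)
    keep_i, keep_j = iu[:n_edges], ju[:n_edges]
    matrix[keep_i, keep_j] = 1
    matrix[keep_j, keep_i] = 1
    alpha = float(magnitudes[n_edges - 1])
    return AdjacencyMatrix(list(S.gene_ids), matrix, omega=omega, alpha=alpha)


def threshold_fixed(S: ScoreMatrix, cutoff: float) -> AdjacencyMatrix:
    """Binarize with a fixed threshold: edge ⇔ |score| > cutoff (strict)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    matrix = (np.abs(S.scores) > cutoff).astype(np.int8)
    np.fill_diagonal(matrix, 0)
    return AdjacencyMatrix(list(S.gene_ids), matrix, cutoff=cutoff)


def bootstrap_adjacency(
    X: ExpressionMatrix,
    omega: float,
    B: int = 50,
    seed: int = 0,
    method: str = "pearson",
) -> AdjacencyMatrix:
    """Bootstrap-aggregated network at controlled sparsity.

    Samples are resampled with replacement B times; each resample yields an
    adjacency via :func:`threshold_to_sparsity`, and the B adjacencies are
    summed into an aggregated count matrix with values in [0, B].  Final
    edges are the pairs whose count reaches β, the smallest integer cutoff
    for which the realized sparsity does not exceed ω (the conservative
    direction).  The aggregated counts are retained on the result as
    ``counts``.

    One master seed spawns independent per-replicate substreams, so
    enlarging B never reshuffles earlier replicates.
    """
    if B < 1:
        raise ValueError("number of bootstrap repetitions B must be >= 1")
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}")
    score_fn = _METHODS[method]
    n = X.n_genes
    counts = np.zeros((n, n), dtype=np.int32)
    streams = np.random.SeedSequence(seed).spawn(B)
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        idx = rng.integers(0, X.n_samples, size=X.n_samples)
        resample = ExpressionMatrix(
            X.gene_ids,
            [f"bs{b}_{k}" for k in range(X.n_samples)],
            X.values[:, idx],
        )
        scores = score_fn(resample)  # zero-variance genes zeroed inside, logged
        adjacency = threshold_to_sparsity(scores, omega)
        counts += adjacency.matrix

    m_possible = n * (n - 1) // 2
    target_edges = omega * m_possible
    beta = 1
    for candidate in range(1, B + 1):
        kept = int(np.triu(counts >= candidate, k=1).sum())
        beta = candidate
        if kept <= target_edges:
            break
    matrix = (counts >= beta).astype(np.int8)
    np.fill_diagonal(matrix, 0)
    result = AdjacencyMatrix(
        list(X.gene_ids), matrix, omega=omega, beta=beta, counts=counts
    )
    logger.info(
        "bootstrap network: B=%d, beta=%d, %d edges (sparsity %.4g, target %.4g)",
        B, beta, result.n_edges, result.sparsity, omega,
    )
    return result


def intersect_condition_networks(networks: list[AdjacencyMatrix]) -> AdjacencyMatrix:
    """Edges present in every condition-specific network.

    Equivalent to summing the adjacency matrices and keeping pairs whose
    aggregated score equals the number of inputs.
    """
    if len(networks) < 2:
        raise ValueError("intersection requires at least 2 networks")
    reference = networks[0].gene_ids
    for net in networks[1:]:
        if list(net.gene_ids) != list(reference):
            raise ValueError("networks have mismatched gene order")
    aggregated = np.sum([net.matrix.astype(np.int32) for net in networks], axis=0)
    matrix = (aggregated == len(networks)).astype(np.int8)
    return AdjacencyMatrix(list(reference), matrix)


def network_summary(A: AdjacencyMatrix) -> dict:
    """Edge count, realized sparsity, degrees and non-isolated node count."""
    degrees = A.degrees()
    return {
        "n_genes": A.n_genes,
        "n_edges": A.n_edges,
        "n_possible_edges": A.n_possible_edges,
        "sparsity": A.sparsity,
        "degrees": dict(zip(A.gene_ids, degrees.tolist())),
        "n_nonisolated": int((degrees > 0).sum()),
    }
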