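"""Gene × gene similarity matrices: Pearson, partial, bicor, TOM, consensus.

Four estimators feed the network-construction stage:

* Pearson product-moment correlation;
* full-order partial correlation from the (pseudo-)inverse of the
  correlation matrix, attenuating indirect relationships;
* biweight midcorrelation (bicor), a robust correlation using median/MAD
  standardization with Tukey biweights;
* the topological overlap measure (TOM) on a soft-thresholded unsigned
  adjacency, optionally combined across condition-specific networks by an
  element-wise-minimum consensus.

The unsigned convention is used throughout: thresholding downstream acts on
absolute scores, and soft adjacencies are |c|^power.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix

logger = logging.getLogger("csenet")

__all__ = [
    "ScoreMatrix",
    "pearson_matrix",
    "partial_matrix",
    "bicor_matrix",
    "tom_similarity",
    "consensus_tom",
]

#: relative singular-value cutoff for the Moore–Penrose pseudo-inverse
PINV_RCOND = 1e-10

#: Tukey biweight tuning constant (in units of the MAD), the standard choice
BICOR_TUNING = 9.0


@dataclass
class ScoreMatrix:
    """Symmetric gene × gene similarity matrix with a method tag."""

    gene_ids: list[str]
    scores: np.ndarray
    method: str
    power: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.gene_ids)
        if self.scores.shape != (n, n):
            raise ValueError(f"score matrix shape {self.scores.shape} != ({n}, {n})")
        if not np.allclose(self.scores, self.scores.T, atol=1e-10):
            raise ValueError("score matrix is not symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _correlation_with_zero_variance_guard(values: np.ndarray,
                                          gene_ids: list[str]) -> np.ndarray:
    """Pearson correlation; zero-variance genes get zero rows (unit diagonal)."""
    variances = values.var(axis=1)
    flat = np.flatnonzero(variances == 0.0)
    if flat.size:
        logger.warning(
            "%d zero-variance gene(s) set to zero correlation: %s",
            flat.size, [gene_ids[i] for i in flat[:10]],
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(values)
        corr[flat, :] = 0.0
        corr[:, flat] = 0.0
    else:
        corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def pearson_matrix(X: ExpressionMatrix) -> ScoreMatrix:
    """Pairwise Pearson product-moment correlations between all genes."""
    corr = _correlation_with_zero_variance_guard(X.values, X.gene_ids)
    return ScoreMatrix(list(X.gene_ids), corr, "pearson")


def partial_matrix(X: ExpressionMatrix) -> ScoreMatrix:
    """Full-order partial correlations between all genes.

    ρ_ij = −Ω_ij / sqrt(Ω_ii Ω_jj) with Ω the inverse of the gene
    correlation matrix.  When the correlation matrix is singular (p ≥ n or
    collinear genes) the Moore–Penrose pseudo-inverse is used and a warning
    is emitted.  With exactly two genes the partial correlation has nothing
    to condition on and equals the Pearson correlation.
    """
    if X.n_genes == 2:
        return ScoreMatrix(list(X.gene_ids), pearson_matrix(X).scores, "partial")
    if X.n_genes < 2:
        raise ValueError("partial correlation needs at least 2 genes")
    corr = _correlation_with_zero_variance_guard(X.values, X.gene_ids)
    # rank deficiency when p >= n or exact collinearity
    rank = np.linalg.matrix_rank(corr, tol=PINV_RCOND * X.n_genes)
    if rank < X.n_genes:
        warnings.warn(
            f"correlation matrix is singular (rank {rank} < {X.n_genes}); "
            "using Moore-Penrose pseudo-inverse",
            UserWarning,
            stacklevel=2,
        )
        omega = np.linalg.pinv(corr, rcond=PINV_RCOND, hermitian=True)
    else:
        omega = np.linalg.inv(corr)
    d = np.sqrt(np.abs(np.diag(omega)))
    with np.errstate(invalid="ignore", divide="ignore"):
        partial = -omega / np.outer(d, d)
    partial[~np.isfinite(partial)] = 0.0
    partial = (partial + partial.T) / 2.0
    np.fill_diagonal(partial, 1.0)
    return ScoreMatrix(list(X.gene_ids), np.clip(partial, -1.0, 1.0), "partial")


def bicor_matrix(X: ExpressionMatrix) -> ScoreMatrix:
    """Biweight midcorrelations between all genes.

    Each gene is median-centered and weighted by Tukey biweights
    w = (1 − u²)² for |u| < 1 with u = (x − median) / (9·MAD); the
    midcorrelation is the correlation of the weighted deviations.  Genes
    whose MAD is zero cannot be biweight-standardized and fall back to
    Pearson for all their pairs (logged); zero-variance genes get zero
    rows as in :func:`pearson_matrix`.
    """
    values = X.values
    n_genes = X.n_genes
    medians = np.median(values, axis=1, keepdims=True)
    deviations = values - medians
    mad = np.median(np.abs(deviations), axis=1)

    fallback = np.flatnonzero(mad == 0.0)
    robust = np.flatnonzero(mad > 0.0)
    if fallback.size:
        logger.warning(
            "%d gene(s) with MAD=0 fall back to Pearson: %s",
            fallback.size, [X.gene_ids[i] for i in fallback[:10]],
        )

    weighted = np.zeros_like(values)
    if robust.size:
        u = deviations[robust] / (BICOR_TUNING * mad[robust, None])
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        weighted[robust] = deviations[robust] * w
    # Pearson-standardized rows for the MAD=0 fallback genes
    if fallback.size:
        centered = values[fallback] - values[fallback].mean(axis=1, keepdims=True)
        weighted[fallback] = centered

    norms = np.sqrt((weighted**2).sum(axis=1))
    zero_norm = norms == 0.0
    safe = np.where(zero_norm, 1.0, norms)
    standardized = weighted / safe[:, None]
    corr = standardized @ standardized.T
    corr[zero_norm, :] = 0.0
    corr[:, zero_norm] = 0.0
    # pairs involving a fallback gene use Pearson on BOTH genes of the pair
    if fallback.size:
        pear = _correlation_with_zero_variance_guard(values, X.gene_ids)
        corr[fallback, :] = pear[fallback, :]
        corr[:, fallback] = pear[:, fallback]
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return ScoreMatrix(list(X.gene_ids), np.clip(corr, -1.0, 1.0), "bicor")


def tom_similarity(C: ScoreMatrix, power: float) -> ScoreMatrix:
    """Topological overlap similarity on the soft adjacency a = |c|^power.

    TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij), where
    ℓ_ij = Σ_{u≠i,j} a_iu a_uj counts shared-neighbour weight and
    k_i = Σ_{u≠i} a_iu is the soft connectivity; the diagonal is 1.
    Values lie in [0, 1] for any unsigned soft adjacency.
    """
    if power <= 0:
        raise ValueError("soft-threshold power must be positive")
    a = np.abs(C.scores) ** power
    np.fill_diagonal(a, 0.0)
    link = a @ a  # a_ii = 0, so terms u = i and u = j vanish
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (link + a) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2.0
    return ScoreMatrix(list(C.gene_ids), np.clip(tom, 0.0, 1.0), "tom", power=power)


def consensus_tom(toms: list[ScoreMatrix]) -> ScoreMatrix:
    """Consensus of condition-specific TOM matrices: element-wise minimum."""
    if len(toms) < 2:
        raise ValueError("consensus requires at least 2 TOM matrices")
    reference = toms[0].gene_ids
    for t in toms[1:]:
        if list(t.gene_ids) != list(reference):
            raise ValueError("TOM matrices have mismatched gene order")
    minimum = np.minimum.reduce([t.scores for t in toms])
    return ScoreMatrix(list(reference), minimum, "tom", power=toms[0].power)
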