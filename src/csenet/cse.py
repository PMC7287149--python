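"""Centralization within sub-experiments (CSE) and tissue-dominance labels.

CSE is the package's core pre-processing transform: each gene is
mean-centered separately within every sub-experiment (replicate group),

    x'_ijk = x_ijk - mean_k(x_ijk),

so the within-sub-experiment mean of the output is exactly zero.  This
removes all between-condition mean differences — treatment, tissue and
batch effects alike — leaving only the replicate-level covariation from
which the core co-expression network is estimated.  CSE centers but never
rescales: the replicate-level variance structure is preserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ExperimentDesign, ExpressionMatrix

logger = logging.getLogger("csenet")

__all__ = [
    "centralize_within_subexperiments",
    "DominanceResult",
    "classify_tissue_dominance",
]


def centralize_within_subexperiments(
    X: ExpressionMatrix,
    design: ExperimentDesign,
    drop_singletons: bool = False,
) -> ExpressionMatrix:
    """Mean-center each gene within each sub-experiment.

    Parameters
    ----------
    X:
        Normalized expression matrix (genes × samples).
    design:
        Sample → sub-experiment mapping covering every sample of ``X``.
    drop_singletons:
        Sub-experiments with a single replicate centre to exactly zero,
        which dilutes downstream correlations; when True their samples are
        removed from the output instead of being kept as zero columns.

    Returns
    -------
    ExpressionMatrix
        Same genes (and samples, unless singletons are dropped); within
        every sub-experiment each gene's mean is exactly zero.  The
        transform is idempotent and invariant to adding any constant per
        (gene, sub-experiment) block.
    """
    design.check_pairing(X)
    values = X.values.copy()
    col = {s: j for j, s in enumerate(X.sample_ids)}
    singleton_cols: list[int] = []
    for sub, members in design.groups().items():
        cols = [col[s] for s in members]
        values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)
        if len(cols) == 1:
            singleton_cols.extend(cols)
    if singleton_cols:
        action = "dropped" if drop_singletons else "zeroed"
        warnings.warn(
            f"{len(singleton_cols)} sample(s) in singleton sub-experiments were {action}",
            UserWarning,
            stacklevel=2,
        )
    if drop_singletons and singleton_cols:
        keep = [j for j in range(X.n_samples) if j not in set(singleton_cols)]
        return ExpressionMatrix(
            X.gene_ids, [X.sample_ids[j] for j in keep], values[:, keep]
        )
    return ExpressionMatrix(X.gene_ids, list(X.sample_ids), values)


@dataclass
class DominanceResult:
    """Per-gene below-/above-ground dominance classification.

    ``delta`` holds Δ_i = mean below-ground − mean above-ground expression
    per gene; ``sd_delta`` is the sample standard deviation (n−1) of all
    Δ values.  A gene is *below-ground dominant* when Δ_i > s_Δ,
    *above-ground dominant* when Δ_i < −s_Δ, and *neither* otherwise.
    """

    gene_ids: list[str]
    delta: np.ndarray
    sd_delta: float
    labels: list[str]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.gene_ids, self.labels))


def classify_tissue_dominance(
    X: ExpressionMatrix,
    below_samples: list[str],
    above_samples: list[str],
) -> DominanceResult:
    """Classify genes as below-/above-ground dominant from raw expression.

    Dominance reflects absolute tissue expression, so it is computed on the
    non-centered matrix; the threshold is one standard deviation of the
    Δ distribution across genes.
    """
    if not below_samples or not above_samples:
        raise ValueError("both tissue sample groups must be non-empty")
    overlap = set(below_samples) & set(above_samples)
    if overlap:
        raise ValueError(f"sample groups overlap: {sorted(overlap)}")
    missing = (set(below_samples) | set(above_samples)) - set(X.sample_ids)
    if missing:
        raise ValueError(f"samples absent from matrix: {sorted(missing)}")
    if X.n_genes < 2:
        raise ValueError("dominance classification needs at least 2 genes (s_delta uses n-1)")

    col = {s: j for j, s in enumerate(X.sample_ids)}
    below_idx = [col[s] for s in below_samples]
    above_idx = [col[s] for s in above_samples]
    delta = X.values[:, below_idx].mean(axis=1) - X.values[:, above_idx].mean(axis=1)
    sd_delta = float(np.std(delta, ddof=1))
    if sd_delta == 0.0:
        warnings.warn(
            "all genes have identical tissue difference; labelling all as neither",
            UserWarning,
            stacklevel=2,
        )
        labels = ["neither"] * X.n_genes
    else:
        labels = [
            "below" if d > sd_delta else "above" if d < -sd_delta else "neither"
            for d in delta
        ]
    counts = {lab: labels.count(lab) for lab in ("below", "above", "neither")}
    logger.info("tissue dominance: s_delta=%.4g, counts=%s", sd_delta, counts)
    return DominanceResult(list(X.gene_ids), delta, sd_delta, labels)
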