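"""Synthetic expression compendia with known co-expression ground truth.

The generator emulates the structure of a large multi-condition expression
compendium: s sub-experiments of r biological replicates each, where

    x_ijk = mu_i + beta_i * delta_j + lambda * f_{m(i),jk} + eps_ijk .

Within-module co-expression comes from a single latent factor f per module
drawn independently for every replicate (rank-1 structure, giving
exchangeable within-module correlation lambda^2 / (lambda^2 + sigma^2)
after centering).  Treatment effects delta_j are constant across the
replicates of a sub-experiment and are shared by an arbitrary subset of
responsive genes (beta_i != 0) that may span modules — exactly the
component that inflates between-module correlations in pooled data and
that within-sub-experiment centering provably removes.  Gaussian noise
eps ~ N(0, sigma^2) completes the model.

Ground truth (module membership, responsive genes, true within-module edge
set, treatment-confounded cross-module pairs) is returned alongside the
data, so network-recovery claims can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExperimentDesign, ExpressionMatrix

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_annotations",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic compendium.

    Defaults describe a desk-scale compendium of 40 conditions in
    triplicate (120 samples): 300 genes of which 10 modules of 15 are
    co-expressed (loading 1 against unit noise, i.e. within-module
    correlation 0.5 after centering), and 50 genes respond to treatment
    with per-condition effects of standard deviation 3 — strong enough
    that pooled correlations between responsive genes dwarf the module
    signal.
    """

    n_genes: int = 300
    module_sizes: tuple[int, ...] = (15,) * 10
    loading: float = 1.0            # lambda, within-module factor loading
    n_subexperiments: int = 40      # s
    replicates: int = 3             # r per sub-experiment
    n_responsive: int = 50          # genes with beta != 0
    effect_sd: float = 3.0          # sd of delta_j across sub-experiments
    noise_sd: float = 1.0           # sigma
    baseline_mean: float = 8.0      # mu_i, typical log2 microarray scale
    baseline_sd: float = 1.0        # spread of mu_i across genes
    seed: int = 1
    effects: tuple[float, ...] | None = None  # fixed delta_j overriding effect_sd

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes sum exceeds the number of genes")
        if any(m < 2 for m in self.module_sizes):
            raise ValueError("every module needs at least 2 genes")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per sub-experiment are required")
        if self.noise_sd <= 0:
            raise ValueError("noise standard deviation must be positive")
        if self.n_responsive > self.n_genes:
            raise ValueError("more responsive genes than genes")
        if self.effects is not None and len(self.effects) != self.n_subexperiments:
            raise ValueError("fixed effects vector must have one delta per sub-experiment")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    module_of: dict[str, int | None]          # gene -> module id (1..m) or None
    beta: dict[str, float]                    # gene -> treatment response
    true_edges: set[tuple[str, str]]          # within-module pairs, canonical order
    confounded_pairs: set[tuple[str, str]]    # both beta != 0, different modules
    effects: np.ndarray = field(repr=False)   # delta_j per sub-experiment

    def modules(self) -> dict[int, set[str]]:
        grouped: dict[int, set[str]] = {}
        for gene, mid in self.module_of.items():
            if mid is not None:
                grouped.setdefault(mid, set()).add(gene)
        return grouped


def generate_dataset(config: GeneratorConfig | None = None,
                     ) -> tuple[ExpressionMatrix, ExperimentDesign, SyntheticTruth]:
    """Draw one synthetic compendium; bit-identical for identical config."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n, s, r = cfg.n_genes, cfg.n_subexperiments, cfg.replicates
    n_samples = s * r
    gene_ids = [f"g{i:04d}" for i in range(1, n + 1)]
    sample_ids = [f"s{j:03d}_r{k}" for j in range(1, s + 1) for k in range(1, r + 1)]
    subexp = {f"s{j:03d}_r{k}": f"sub{j:03d}"
              for j in range(1, s + 1) for k in range(1, r + 1)}

    # module membership: first modules occupy the leading genes
    module_of: dict[str, int | None] = {g: None for g in gene_ids}
    start = 0
    for mid, size in enumerate(cfg.module_sizes, start=1):
        for g in gene_ids[start:start + size]:
            module_of[g] = mid
        start += size

    # treatment-responsive genes drawn across the whole universe
    responsive = rng.choice(n, size=cfg.n_responsive, replace=False)
    beta = {g: 0.0 for g in gene_ids}
    for i in responsive:
        beta[gene_ids[i]] = 1.0

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    if cfg.effects is not None:
        delta = np.asarray(cfg.effects, dtype=float)
    else:
        delta = rng.normal(0.0, cfg.effect_sd, size=s)
    # one latent factor per module per sample (fresh draw each replicate)
    factors = rng.standard_normal((len(cfg.module_sizes), n_samples))
    noise = rng.normal(0.0, cfg.noise_sd, size=(n, n_samples))

    values = np.tile(mu[:, None], (1, n_samples)) + noise
    beta_vec = np.array([beta[g] for g in gene_ids])
    delta_per_sample = np.repeat(delta, r)
    values += np.outer(beta_vec, delta_per_sample)
    for i, g in enumerate(gene_ids):
        mid = module_of[g]
        if mid is not None:
            values[i] += cfg.loading * factors[mid - 1]

    X = ExpressionMatrix(gene_ids, sample_ids, values)
    design = ExperimentDesign(sample_to_subexp=subexp)

    true_edges: set[tuple[str, str]] = set()
    for members in SyntheticTruth(module_of, beta, set(), set(), delta).modules().values():
        ordered = sorted(members)
        for a_idx in range(len(ordered)):
            for b_idx in range(a_idx + 1, len(ordered)):
                true_edges.add((ordered[a_idx], ordered[b_idx]))

    confounded: set[tuple[str, str]] = set()
    responsive_genes = sorted(g for g in gene_ids if beta[g] != 0.0)
    for a_idx in range(len(responsive_genes)):
        for b_idx in range(a_idx + 1, len(responsive_genes)):
            ga, gb = responsive_genes[a_idx], responsive_genes[b_idx]
            if module_of[ga] is None or module_of[ga] != module_of[gb]:
                confounded.add((ga, gb) if ga < gb else (gb, ga))

    truth = SyntheticTruth(module_of, beta, true_edges, confounded, delta)
    return X, design, truth


def generate_annotations(truth: SyntheticTruth, gene_ids: list[str],
                         seed: int = 0, n_decoys: int | None = None,
                         ) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Gene-set catalog and annotation table from synthetic ground truth.

    The catalog holds one set per true module plus size-matched decoy sets
    drawn uniformly without replacement from the gene universe (seeded).
    The annotation table assigns every gene exactly one category: its
    module label, or "background" for genes outside all modules.
    """
    rng = np.random.default_rng(seed)
    modules = truth.modules()
    catalog: dict[str, set[str]] = {}
    for mid in sorted(modules):
        catalog[f"module_{mid:02d}"] = set(modules[mid])
    if n_decoys is None:
        n_decoys = len(modules)
    sizes = [len(modules[mid]) for mid in sorted(modules)]
    for d in range(n_decoys):
        size = sizes[d % len(sizes)] if sizes else 10
        picked = rng.choice(len(gene_ids), size=size, replace=False)
        catalog[f"decoy_{d + 1:02d}"] = {gene_ids[i] for i in picked}

    annotations = {
        g: f"module_{truth.module_of[g]:02d}" if truth.module_of[g] else "background"
        for g in gene_ids
    }
    return catalog, annotations
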