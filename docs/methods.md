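# Methods

## Model and procedure

`csenet` estimates the *core* co-expression network of a multi-condition
expression compendium: the gene–gene covariation that persists across the
majority of conditions once condition-level mean effects are removed.

The data model is a genes × samples matrix x_ijk (gene i, sub-experiment j,
replicate k), where a *sub-experiment* is a replicate group — assays taken
under identical settings. Centralization within sub-experiments (CSE)
replaces x_ijk by x_ijk − x̄_ij·. Because the subtraction is per gene and
per sub-experiment, any additive effect that is constant across the
replicates of a condition — treatment response, tissue baseline, batch
offset — is removed exactly; the within-group mean of the output is zero by
construction (numerically ≤ 1e-10 in double precision, and the transform is
idempotent to the same rounding). CSE centers but does not rescale: the
paper-of-record convention for this transform is mean-centering only, and
preserving replicate-level variances keeps Pearson correlations
interpretable afterwards. The price of centering is one degree of freedom
per gene per sub-experiment, i.e. a reduced signal-to-noise ratio when
replicate groups are small; with r = 2–3 replicates roughly a third to a
half of the degrees of freedom are spent.

Networks are built in three steps: (i) optional CSE; (ii) a gene × gene
similarity matrix; (iii) binarization at a controlled sparsity ω, keeping
the floor(ω·M) pairs of largest absolute score among the M = n(n−1)/2
possible. The sparsity-controlled cutoff α is found by exact order-statistic
selection rather than by iterating a threshold — the result is identical and
deterministic. Ties at the cutoff are broken by (|score| descending, first
gene, second gene), so the edge count is exact even for discrete scores.

Similarity estimators:

- **Pearson** product-moment correlation; genes with zero variance get zero
  rows (unit diagonal) and a log entry.
- **Partial correlation** (full order): ρ_ij = −Ω_ij/√(Ω_ii Ω_jj) with Ω the
  inverse of the correlation matrix. When the matrix is singular (p ≥ n or
  collinearity) the Moore–Penrose pseudo-inverse with relative singular-value
  cutoff 1e-10 is used and a warning emitted; with two genes the definition
  degenerates to Pearson.
- **Biweight midcorrelation** with the standard tuning constant 9 (in MAD
  units). Genes whose MAD is zero cannot be biweight-standardized and fall
  back to Pearson for all their pairs, following the estimator's established
  convention.
- **TOM**: soft adjacency a_ij = |c_ij|^power (unsigned convention
  throughout), TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij). Soft powers
  are caller-supplied; the defaults mirror common practice for this pipeline
  (5 for whole-data networks, 6/11 for centered/uncentered consensus
  sub-networks) and no automatic scale-free fit is performed. Consensus
  across condition-specific TOMs is the element-wise minimum.

Network variants: a **bootstrap** network resamples the samples with
replacement B times (default 50), thresholds each resample at ω, sums the B
adjacencies into a count matrix (0..B), and keeps pairs whose count reaches
β — the smallest integer for which the realized sparsity does not exceed ω.
Taking sparsity from below is the conservative direction; the alternative
(closest from above) would admit more edges than the target. One master seed
spawns per-replicate substreams, so increasing B never reshuffles earlier
replicates. A **fixed-cutoff** network keeps |score| > cutoff (strict), and
condition-specific networks are combined by **intersection** (an edge must
appear in all inputs, equivalently its aggregated score equals the input
count).

## Statistical evaluation

In a network of controlled sparsity ω, a randomly placed edge falls inside a
given gene set of n_A nodes with probability ω, so the internal edge count
K is Bin(C(n_A,2), ω) under the null. The *pronounced* test is the exact
one-sided binomial tail; the pronounced flag itself (K > ω·M) is
descriptive and threshold-free. Between-set tests use M = n1·n2 with genes
shared by the pair removed from both sets — the simplest null consistent
with random edge placement; the package treats shared genes as belonging to
neither set for that pair. Two networks are compared on the same gene set by
Fisher's exact test on [[K_A, M−K_A],[K_B, M−K_B]] (two-sided), and
non-isolated node counts likewise. Proportions are compared with the pooled
two-proportion z statistic and a two-sided normal p; a degenerate pooled
proportion (0 or 1) returns z undefined → p = 1 with a warning. Single-gene
category tests use the unconditional Bin(m, ω) null from the same edge
model; a degree-conditioned hypergeometric variant is available behind a
flag but is not the default, because the unconditional binomial is the
form the evaluation framework defines. All binomial and Fisher p-values are
exact, never normal approximations. Catalog-level results report raw p as
the primary column with Benjamini–Hochberg q-values adjusted separately
within the within-set and between-set families.

Guilt-by-association profiling of an unannotated gene compares, per
functional category, the category's share among the gene's neighbours
(k1/degree) with its share of the annotated universe, via the two-proportion
z; positive z marks over-representation.

Tissue-dominance classification computes Δ_i = mean below-ground − mean
above-ground expression on the **raw** (non-centered) matrix — dominance is
a statement about absolute tissue expression, which CSE removes — and labels
genes below/above dominant when |Δ_i| exceeds one standard deviation of the
Δ distribution (sample estimator, n−1 denominator; the conventional choice
where only "estimated standard deviation" is specified).

## Communities

Reference communities are detected on the core (CSE) network with Walktrap
(walk length 4, the algorithm's default), cutting the agglomerative
dendrogram at maximal modularity via igraph. Isolated nodes are excluded and
labelled "unassigned" rather than forced into singleton communities, since
only nodes with at least one edge carry network information. The partition
is deterministic given adjacency and walk length, and invariant to gene
permutation up to relabeling (communities are numbered by first appearance
in gene order). Overlaying a condition-specific network onto the partition
yields per-node community labels and per-community occupancy counts;
community-level stress enrichment reuses the two-proportion z.

## Synthetic data

The generator draws x_ijk = μ_i + β_i δ_j + λ f_{m(i),jk} + ε_ijk:
baselines μ_i ~ N(8, 1) (a typical log2 microarray scale), per-condition
treatment effects δ_j ~ N(0, effect_sd²) drawn once and fixed (a fixed
design vector can be supplied for reproducible examples), responsive genes
with β_i = 1, one latent factor per module drawn fresh for every sample
(rank-1 within-module structure — the simplest mechanism giving
exchangeable within-module correlation λ²/(λ² + σ²) after centering), and
noise ε ~ N(0, σ²).

Defaults: 300 genes, 10 modules of 15, λ = 1, σ = 1, s = 40 sub-experiments
of r = 3 replicates (120 samples), 50 responsive genes, effect_sd = 3.
These give pooled correlations of ≈ 0.82–0.90 between responsive genes —
treatment confounding that dominates the module signal (0.5) — which is the
regime the method exists for. What the generator does **not** emulate:
probe-level noise, saturation, count distributions, correlated noise across
genes, or modules of heterogeneous loading; passing tests therefore
demonstrate the estimators' behaviour under the stated additive Gaussian
model, not microarray realism.

Module sizes, sample counts and seeds used in tests and examples are chosen
at desk scale (hundreds of genes, ≤ 600 samples), where every computation
runs in seconds.

## Numerical choices and degenerate inputs

- Quantile normalization maps each column onto the across-sample mean of
  order statistics; ties within a column all receive the mean of the
  reference values at their tied rank positions (rank-average dialect:
  deterministic and symmetric). With ties present this averaging breaks
  exact idempotence — a known property of the dialect; on tie-free data the
  transform is exactly idempotent and all column-sorted vectors are
  bit-identical.
- Sub-experiments of size 1 centre to exactly zero; they are kept by default
  (warning) and removable with `drop_singletons`, since zero columns dilute
  correlations.
- Score matrices are symmetrized ((S + Sᵀ)/2) and clipped to their valid
  range after floating-point arithmetic; adjacency invariants (binary,
  symmetric, zero diagonal) are enforced at construction.
- ω·M is floored with a 1e-12 guard so that exact integer products are not
  lost to floating-point representation.

## Known limitations

- Full-order partial correlation in the p ≈ n regime rests on the
  pseudo-inverse contract above; it is documented, not claimed equivalent to
  any particular shrinkage estimator.
- The between-set possible-edge count M = n1·n2 is a modelling choice; other
  nulls (degree-preserving rewiring) are out of scope.
- Under the default synthetic conditions the ω = 0.005 cutoff retains only
  224 of the 1050 true within-module pairs, and because all pairs of a
  module share one factor realization, per-module edge counts are
  overdispersed: every true module is reliably pronounced (K > ω·M), but at
  a fixed seed the weakest module may not reach p < 1e-4. Raising λ or ω
  removes the effect; the defaults are kept as the harder, more honest
  regime.
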