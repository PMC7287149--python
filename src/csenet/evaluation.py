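"""Statistical evaluation of co-expression networks.

The central device is the *pronounced sub-network* test: in a network whose
sparsity is controlled at ω, the edge count K inside any a-priori gene set
with M possible internal edges is Bin(M, ω) under the null of a random
network, so an exact one-sided binomial tail quantifies how strongly the
set's internal connectivity exceeds chance (a set is *pronounced* when
K > ω·M).  Networks are compared on a common gene set with Fisher's exact
test, proportions with the pooled two-proportion z statistic, and
unannotated genes are profiled by guilt-by-association over the functional
categories of their network neighbours.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import AdjacencyMatrix

logger = logging.getLogger("csenet")

__all__ = [
    "SubnetworkTestResult",
    "ProportionTestResult",
    "count_edges_within",
    "count_edges_between",
    "pronounced_test",
    "compare_networks_fisher",
    "compare_node_counts_fisher",
    "two_proportion_z",
    "gene_category_test",
    "guilt_by_association_profile",
    "evaluate_catalog",
]


@dataclass
class SubnetworkTestResult:
    """Outcome of a binomial sub-network edge-enrichment test."""

    name: str
    n_nodes: int
    n_possible: int          # M
    observed: int            # K
    expected: float          # omega * M
    p_value: float
    pronounced: bool
    alternative: str = "greater"


@dataclass
class ProportionTestResult:
    """Pooled two-proportion z comparison of k1/n1 versus k2/n2."""

    k1: int
    n1: int
    k2: int
    n2: int
    pooled: float
    z: float
    p_value: float


def _gene_indices(A: AdjacencyMatrix, genes: set[str], label: str) -> list[int]:
    index = {g: i for i, g in enumerate(A.gene_ids)}
    outside = set(genes) - index.keys()
    if outside:
        warnings.warn(
            f"{len(outside)} gene(s) of {label} absent from the network were dropped",
            UserWarning,
            stacklevel=3,
        )
    return sorted(index[g] for g in genes if g in index)


def count_edges_within(A: AdjacencyMatrix, genes: set[str]) -> tuple[int, int]:
    """Observed edges K and possible edges M = C(n_A, 2) inside a gene set."""
    idx = _gene_indices(A, genes, "gene set")
    if len(idx) < 2:
        raise ValueError("fewer than 2 set genes present in the network")
    sub = A.matrix[np.ix_(idx, idx)]
    K = int(np.triu(sub, k=1).sum())
    M = len(idx) * (len(idx) - 1) // 2
    return K, M


def count_edges_between(A: AdjacencyMatrix, set1: set[str],
                        set2: set[str]) -> tuple[int, int]:
    """Observed cross edges K and possible edges M = n1·n2 between two sets.

    The sets must be disjoint; genes appearing in both must be removed by
    the caller (``evaluate_catalog`` disjointifies automatically).
    """
    overlap = set(set1) & set(set2)
    if overlap:
        raise ValueError(
            f"sets overlap in {len(overlap)} gene(s) (e.g. {sorted(overlap)[:3]}); "
            "remove shared genes from both sets before testing"
        )
    idx1 = _gene_indices(A, set1, "set 1")
    idx2 = _gene_indices(A, set2, "set 2")
    if not idx1 or not idx2:
        raise ValueError("each set needs at least 1 gene present in the network")
    K = int(A.matrix[np.ix_(idx1, idx2)].sum())
    M = len(idx1) * len(idx2)
    return K, M


def pronounced_test(K: int, M: int, omega: float,
                    alternative: str = "greater",
                    name: str = "") -> SubnetworkTestResult:
    """Exact binomial test of K observed edges among M possible at sparsity ω.

    Under the null of a random network, K ~ Bin(M, ω); the p-value is the
    exact one-sided binomial tail.  The *pronounced* flag records whether
    the observed count exceeds its null expectation ω·M (a descriptive
    property, independent of the significance level).
    """
    if not 0 <= K <= M:
        raise ValueError(f"need 0 <= K <= M, got K={K}, M={M}")
    if not 0.0 < omega < 1.0:
        raise ValueError("omega must lie strictly between 0 and 1")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    p = float(stats.binomtest(K, M, omega, alternative=alternative).pvalue)
    expected = omega * M
    n_nodes = int(round((1 + np.sqrt(1 + 8 * M)) / 2)) if M else 0
    return SubnetworkTestResult(
        name=name, n_nodes=n_nodes, n_possible=M, observed=K,
        expected=expected, p_value=p, pronounced=K > expected,
        alternative=alternative,
    )


def compare_networks_fisher(K_A: int, K_B: int, M: int) -> float:
    """Two-sided Fisher exact p comparing edge counts of two networks.

    Tests whether a sub-network of M possible edges realizes the same edge
    proportion in network A (K_A edges) and network B (K_B edges), via the
    2×2 table [[K_A, M−K_A], [K_B, M−K_B]].
    """
    if not (0 <= K_A <= M and 0 <= K_B <= M):
        raise ValueError("edge counts must lie in [0, M]")
    table = [[K_A, M - K_A], [K_B, M - K_B]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def compare_node_counts_fisher(nonisolated_A: int, n: int,
                               nonisolated_B: int) -> float:
    """Two-sided Fisher exact p comparing non-isolated node counts."""
    if not (0 <= nonisolated_A <= n and 0 <= nonisolated_B <= n):
        raise ValueError("node counts must lie in [0, n]")
    table = [[nonisolated_A, n - nonisolated_A], [nonisolated_B, n - nonisolated_B]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> ProportionTestResult:
    """Pooled two-proportion z test with two-sided normal p-value.

    z = (p̂1 − p̂2) / sqrt(π̂(1 − π̂)(1/n1 + 1/n2)) with the pooled
    proportion π̂ = (k1 + k2)/(n1 + n2).  Degenerate pooled proportions
    (0 or 1) leave z undefined; z = 0, p = 1 is returned with a warning.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must lie in [0, n]")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn(
            "pooled proportion is degenerate (0 or 1); z undefined, returning p=1",
            UserWarning,
            stacklevel=2,
        )
        return ProportionTestResult(k1, n1, k2, n2, pooled, 0.0, 1.0)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ProportionTestResult(k1, n1, k2, n2, pooled, float(z), p)


def gene_category_test(gene: str, category: set[str], A: AdjacencyMatrix,
                       omega: float, alternative: str = "greater",
                       condition_on_degree: bool = False) -> SubnetworkTestResult:
    """Does one gene have more (or fewer) edges into a category than chance?

    The null is unconditional: each of the m gene–category pairs is an edge
    with probability ω, so K ~ Bin(m, ω).  ``condition_on_degree`` switches
    to a hypergeometric null that conditions on the gene's realized degree
    (drawing its d edges uniformly among the n−1 possible partners).
    """
    if gene not in A.gene_ids:
        raise ValueError(f"gene {gene!r} is not in the network")
    members = set(category) - {gene}
    idx_gene = A.gene_ids.index(gene)
    idx_members = _gene_indices(A, members, f"category of {gene}")
    m = len(idx_members)
    if m < 1:
        raise ValueError("category has no other network genes")
    K = int(A.matrix[idx_gene, idx_members].sum())
    if condition_on_degree:
        degree = int(A.matrix[idx_gene].sum())
        n_other = A.n_genes - 1
        if alternative == "greater":
            p = float(stats.hypergeom.sf(K - 1, n_other, m, degree))
        else:
            p = float(stats.hypergeom.cdf(K, n_other, m, degree))
        expected = degree * m / n_other
        return SubnetworkTestResult(
            name=gene, n_nodes=m, n_possible=m, observed=K,
            expected=expected, p_value=p, pronounced=K > expected,
            alternative=alternative,
        )
    result = pronounced_test(K, m, omega, alternative=alternative, name=gene)
    result.n_nodes = m
    return result


def guilt_by_association_profile(gene: str, A: AdjacencyMatrix,
                                 annotations: dict[str, str]) -> pd.DataFrame:
    """Functional-category profile of a gene's network neighbours.

    For every category, the proportion of the gene's neighbours annotated
    to it (k1/n1, n1 = degree) is compared against the category's share of
    the annotated universe (k2/n2) with the two-proportion z test.  Rows
    are sorted by p-value; a positive z marks over-representation among the
    neighbours — evidence, in a guilt-by-association sense, for the gene
    participating in that category's function.
    """
    if gene not in A.gene_ids:
        raise ValueError(f"gene {gene!r} is not in the network")
    idx_gene = A.gene_ids.index(gene)
    neighbour_idx = np.flatnonzero(A.matrix[idx_gene])
    if neighbour_idx.size == 0:
        raise ValueError(f"gene {gene!r} has no edges")
    neighbours = [A.gene_ids[i] for i in neighbour_idx]
    degree = len(neighbours)
    universe = [g for g in annotations if g != gene]
    n_universe = len(universe)
    category_counts: dict[str, int] = {}
    for g in universe:
        category_counts[annotations[g]] = category_counts.get(annotations[g], 0) + 1

    rows = []
    for category in sorted(category_counts):
        k1 = sum(1 for g in neighbours if annotations.get(g) == category)
        k2 = category_counts[category]
        res = two_proportion_z(k1, degree, k2, n_universe)
        rows.append({
            "category": category,
            "neighbours_in_category": k1,
            "degree": degree,
            "neighbour_proportion": k1 / degree,
            "background_count": k2,
            "background_proportion": k2 / n_universe,
            "z": res.z,
            "p_value": res.p_value,
        })
    frame = pd.DataFrame(rows).sort_values("p_value", kind="stable")
    return frame.reset_index(drop=True)


def evaluate_catalog(A: AdjacencyMatrix, catalog: dict[str, set[str]],
                     omega: float, between: bool = True,
                     alternative: str = "greater") -> pd.DataFrame:
    """Pronounced-sub-network tests for every set (and every pair) of a catalog.

    Within-set tests use M = C(n_A, 2); between-set tests use M = n1·n2
    after removing genes shared by the pair from both sets.  Raw p-values
    are the primary column; Benjamini–Hochberg q-values are adjusted
    separately within the within-set and between-set families.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    network_genes = set(A.gene_ids)
    usable: dict[str, set[str]] = {}
    for name, genes in catalog.items():
        present = set(genes) & network_genes
        if len(present) < 2:
            logger.warning("set %r has <2 network genes; skipped", name)
            continue
        usable[name] = present

    rows = []
    for name, genes in usable.items():
        K, M = count_edges_within(A, genes)
        res = pronounced_test(K, M, omega, alternative=alternative, name=name)
        rows.append({
            "kind": "within", "set": name, "n": len(genes), "M": M, "K": K,
            "expected": res.expected, "p": res.p_value, "pronounced": res.pronounced,
        })
    if between:
        for name1, name2 in itertools.combinations(sorted(usable), 2):
            s1 = usable[name1] - usable[name2]
            s2 = usable[name2] - usable[name1]
            shared = usable[name1] & usable[name2]
            if shared:
                logger.info(
                    "pair (%s, %s): %d shared gene(s) removed from both sets",
                    name1, name2, len(shared),
                )
            if not s1 or not s2:
                continue
            K, M = count_edges_between(A, s1, s2)
            res = pronounced_test(K, M, omega, alternative=alternative,
                                  name=f"{name1}|{name2}")
            rows.append({
                "kind": "between", "set": f"{name1}|{name2}",
                "n": len(s1) + len(s2), "M": M, "K": K,
                "expected": res.expected, "p": res.p_value,
                "pronounced": res.pronounced,
            })
    frame = pd.DataFrame(rows)
    frame["q"] = np.nan
    for kind in frame["kind"].unique():
        mask = frame["kind"] == kind
        frame.loc[mask, "q"] = multipletests(frame.loc[mask, "p"], method="fdr_bh")[1]
    return frame
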