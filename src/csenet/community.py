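"""Reference communities by random-walk clustering, and condition overlays.

The reference community set is built from a core (CSE) network with the
Walktrap algorithm: short random walks tend to stay inside densely
connected regions, and agglomerative merging of walk-distance-similar
nodes yields a dendrogram that is cut at maximal modularity.  The
partition is then overlaid onto condition-specific (non-CSE) networks to
ask which communities a stress response occupies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .evaluation import ProportionTestResult, two_proportion_z
from .network import AdjacencyMatrix

logger = logging.getLogger("csenet")

__all__ = [
    "CommunityPartition",
    "walktrap_communities",
    "overlay_communities",
    "community_stress_enrichment",
]


@dataclass
class CommunityPartition:
    """Assignment of non-isolated network genes to communities 1..c.

    Isolated nodes are excluded from clustering and listed separately
    rather than forced into singleton communities.
    """

    membership: dict[str, int]
    isolated: list[str]
    steps: int
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> dict[int, set[str]]:
        grouped: dict[int, set[str]] = {}
        for gene, cid in self.membership.items():
            grouped.setdefault(cid, set()).add(gene)
        return grouped

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene": g, "community": c} for g, c in self.membership.items()]
        rows += [{"gene": g, "community": 0} for g in self.isolated]
        return pd.DataFrame(rows)


def walktrap_communities(A: AdjacencyMatrix, steps: int = 4) -> CommunityPartition:
    """Walktrap (Pons–Latapy) clustering of a network.

    Agglomerates nodes by similarity of short random-walk distributions
    (walk length ``steps``) and cuts the resulting dendrogram at the level
    of maximal modularity.  Deterministic given the adjacency and walk
    length.  Communities are numbered 1..c in order of first appearance in
    the gene order.
    """
    if A.n_edges == 0:
        raise ValueError("cannot cluster an edgeless network")
    degrees = A.degrees()
    keep = np.flatnonzero(degrees > 0)
    isolated = [A.gene_ids[i] for i in np.flatnonzero(degrees == 0)]
    sub = A.matrix[np.ix_(keep, keep)]
    graph = ig.Graph.Adjacency(sub.tolist(), mode="undirected")
    dendrogram = graph.community_walktrap(steps=steps)
    clustering = dendrogram.as_clustering()  # cut maximizing modularity
    modularity = float(clustering.modularity)

    # relabel communities 1..c by first occurrence in gene order
    raw = clustering.membership
    relabel: dict[int, int] = {}
    membership: dict[str, int] = {}
    for local, gene_idx in enumerate(keep):
        cid = raw[local]
        if cid not in relabel:
            relabel[cid] = len(relabel) + 1
        membership[A.gene_ids[gene_idx]] = relabel[cid]
    logger.info(
        "walktrap: %d communities over %d nodes (modularity %.4f, %d isolated)",
        len(relabel), len(keep), modularity, len(isolated),
    )
    return CommunityPartition(membership, isolated, steps, modularity)


def overlay_communities(stress_net: AdjacencyMatrix,
                        partition: CommunityPartition,
                        shared_genes: set[str] | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-reference a condition-specific network with a reference partition.

    Returns a node table (gene, community label or "unassigned", degree in
    the stress network, optional membership flag for ``shared_genes``) and
    a per-community occupancy table counting the stress network's
    non-isolated nodes falling in each reference community.
    """
    reference_genes = set(partition.membership) | set(partition.isolated)
    if not reference_genes & set(stress_net.gene_ids):
        raise ValueError("stress network and reference partition share no genes")
    degrees = dict(zip(stress_net.gene_ids, stress_net.degrees().tolist()))

    rows = []
    for gene in stress_net.gene_ids:
        row = {
            "gene": gene,
            "community": partition.membership.get(gene, 0) or "unassigned",
            "degree": degrees[gene],
        }
        if partition.membership.get(gene):
            row["community"] = partition.membership[gene]
        if shared_genes is not None:
            row["shared"] = gene in shared_genes
        rows.append(row)
    nodes = pd.DataFrame(rows)

    occupied = nodes[(nodes["degree"] > 0) & (nodes["community"] != "unassigned")]
    occupancy = (
        occupied.groupby("community").size().rename("n_nodes").reset_index()
        .sort_values("community", kind="stable").reset_index(drop=True)
    )
    return nodes, occupancy


def community_stress_enrichment(partition: CommunityPartition,
                                stress_genes: set[str],
                                universe: set[str]) -> pd.DataFrame:
    """Which reference communities are enriched for stress-responsive genes?

    Per community, the community's share of stress genes (k1/n1) is
    compared against the stress genes' share of the whole universe (k2/n2)
    with the pooled two-proportion z test.
    """
    if not stress_genes:
        raise ValueError("stress gene set is empty")
    if not set(stress_genes) <= set(universe):
        raise ValueError("stress genes must be a subset of the universe")
    rows = []
    for cid, members in sorted(partition.communities().items()):
        members = members & set(universe)
        if not members:
            logger.info("community %d has no universe genes; skipped", cid)
            continue
        k1 = len(members & stress_genes)
        res: ProportionTestResult = two_proportion_z(
            k1, len(members), len(stress_genes), len(universe)
        )
        rows.append({
            "community": cid, "n_genes": len(members), "n_stress": k1,
            "community_proportion": k1 / len(members),
            "background_proportion": len(stress_genes) / len(universe),
            "z": res.z, "p": res.p_value,
        })
    return pd.DataFrame(rows)
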