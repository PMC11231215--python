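"""Cross-network community comparison and similarity-cluster extraction.

Communities from different phenotype networks are compared at three
levels: functional enrichment profiles, gene composition, and induced
edge structure, all with the Jaccard index |A∩B| / |A∪B|.  Gene-sharing
communities form a meta-network whose tau-thresholded connected
components are the *similarity clusters* — groups of communities from
different phenotypes with similar composition, wiring and function.

Edges are identified across networks by their endpoint gene-id pairs
(the networks share a gene universe); MI weights play no role in the
structural comparison — only connection presence is compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

RECORD_COLUMNS = [
    "network_a",
    "community_a",
    "network_b",
    "community_b",
    "gene_jaccard",
    "edge_jaccard",
    "n_shared_genes",
]


def gene_jaccard(a, b) -> float:
    """|A∩B| / |A∪B| for two gene sets; undefined when both are empty."""
    a, b = frozenset(a), frozenset(b)
    if not a and not b:
        raise ValueError("both gene sets are empty")
    return len(a & b) / len(a | b)


def edge_jaccard(edges_a, edges_b) -> float:
    """Jaccard of two induced edge sets (canonical unordered gene pairs).

    Two communities with both edge sets empty share no structure to
    compare; that degenerate case is defined as 0.
    """
    a = {tuple(sorted(e)) for e in edges_a}
    b = {tuple(sorted(e)) for e in edges_b}
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


@dataclass
class SimilarityCluster:
    """A tau-connected group of communities from different networks."""

    cluster_id: int
    members: list  # of (network, community label)
    gene_matrix: pd.DataFrame  # pairwise gene-composition Jaccard
    edge_matrix: pd.DataFrame  # pairwise edge-structure Jaccard
    genes: frozenset  # union of member gene sets

    @property
    def n_networks(self) -> int:
        return len({net for net, _ in self.members})


def all_pairs_similarity(community_sets: dict) -> pd.DataFrame:
    """SimilarityRecords for every cross-network community pair.

    ``community_sets`` maps network label -> CommunitySet (or any iterable
    of objects with .label, .genes, .edges).  Within-network pairs are
    excluded; each unordered pair appears once, in the deterministic order
    of sorted network labels then community labels.
    """
    nets = sorted(community_sets)
    if len(nets) < 2:
        raise ValueError("need community sets from at least 2 networks")
    rows = []
    for i, na in enumerate(nets):
        ca = sorted(community_sets[na], key=lambda c: c.label)
        for nb in nets[i + 1 :]:
            cb = sorted(community_sets[nb], key=lambda c: c.label)
            for a in ca:
                for b in cb:
                    rows.append(
                        (
                            na,
                            a.label,
                            nb,
                            b.label,
                            gene_jaccard(a.genes, b.genes),
                            edge_jaccard(a.edges, b.edges),
                            len(frozenset(a.genes) & frozenset(b.genes)),
                        )
                    )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def build_meta_network(records: pd.DataFrame, community_sets: dict | None = None) -> nx.Graph:
    """Meta-network: nodes are communities (annotated with origin network
    and size), edges link gene-sharing pairs, weighted by gene Jaccard.

    Communities that share zero genes are never connected.
    """
    g = nx.Graph()
    if community_sets is not None:
        for net in sorted(community_sets):
            for comm in sorted(community_sets[net], key=lambda c: c.label):
                g.add_node(comm.label, network=net, size=len(comm.genes))
    for rec in records.itertuples(index=False):
        for label, net in (
            (rec.community_a, rec.network_a),
            (rec.community_b, rec.network_b),
        ):
            if label not in g:
                g.add_node(label, network=net)
        if rec.gene_jaccard > 0:
            g.add_edge(
                rec.community_a,
                rec.community_b,
                weight=rec.gene_jaccard,
                edge_jaccard=rec.edge_jaccard,
            )
    return g


def _pair_matrix(labels, records: pd.DataFrame, column: str) -> pd.DataFrame:
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    lut = {}
    for rec in records.itertuples(index=False):
        lut[(rec.community_a, rec.community_b)] = getattr(rec, column)
        lut[(rec.community_b, rec.community_a)] = getattr(rec, column)
    for a in labels:
        for b in labels:
            if a != b and (a, b) in lut:
                mat.loc[a, b] = lut[(a, b)]
    return mat


def extract_similarity_clusters(
    meta: nx.Graph, records: pd.DataFrame, tau: float = 0.2, community_sets: dict | None = None
) -> list:
    """Similarity clusters: connected components of the meta-network after
    removing edges with gene Jaccard < tau; singletons are dropped.

    Each cluster carries its pairwise gene- and edge-Jaccard matrices
    (heatmap-ready).  Extraction is invariant to community enumeration
    order: components are sorted by decreasing size then smallest label.
    """
    if not 0 <= tau <= 1:
        raise ValueError("tau must lie in [0, 1]")
    strong = nx.Graph()
    strong.add_nodes_from(meta.nodes(data=True))
    for a, b, d in meta.edges(data=True):
        if d["weight"] >= tau:
            strong.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(strong) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), c[0]))
    genes_of = {}
    if community_sets is not None:
        for net in community_sets:
            for comm in community_sets[net]:
                genes_of[comm.label] = frozenset(comm.genes)
    clusters = []
    for cid, labels in enumerate(comps, start=1):
        clusters.append(
            SimilarityCluster(
                cluster_id=cid,
                members=[
                    (strong.nodes[l].get("network", ""), l) for l in labels
                ],
                gene_matrix=_pair_matrix(labels, records, "gene_jaccard"),
                edge_matrix=_pair_matrix(labels, records, "edge_jaccard"),
                genes=frozenset().union(
                    *(genes_of.get(l, frozenset()) for l in labels)
                ),
            )
        )
    return clusters


def enrichment_profile_similarity(significant_by_community: dict) -> pd.DataFrame:
    """Pairwise Jaccard of significant-term sets between communities.

    Input maps community label -> set of significant term ids; output is a
    square matrix aligned with the gene/edge Jaccard matrices.  Pairs
    where both communities have empty term sets score 0.
    """
    labels = sorted(significant_by_community)
    mat = pd.DataFrame(
        np.eye(len(labels)), index=labels, columns=labels
    )
    for i, a in enumerate(labels):
        sa = set(significant_by_community[a])
        for b in labels[i + 1 :]:
            sb = set(significant_by_community[b])
            union = sa | sb
            val = len(sa & sb) / len(union) if union else 0.0
            mat.loc[a, b] = val
            mat.loc[b, a] = val
    return mat


def cluster_overlap_matrix(clusters: list) -> pd.DataFrame:
    """Jaccard of gene compositions between whole similarity clusters
    (the cross-cluster heatmap input)."""
    ids = [f"cluster_{c.cluster_id}" for c in clusters]
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(clusters):
        for j in range(i + 1, len(clusters)):
            b = clusters[j]
            val = gene_jaccard(a.genes, b.genes) if (a.genes or b.genes) else 0.0
            mat.iloc[i, j] = val
            mat.iloc[j, i] = val
    return mat
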