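"""Community detection by two-level map-equation minimization.

The map equation scores a hard partition of a weighted undirected network
by the expected per-step description length (bits) of a random walk coded
with a two-level codebook: an index codebook over module entries and one
codebook per module over its nodes and its exit.  Node visit rates are
strength / total strength; module exit rates come from inter-module edge
weight.  Minimization is greedy: repeated single-node moves to the
neighboring module that most decreases the codelength, followed by module
aggregation, iterated to convergence, with seeded restarts.

Communities of at least ``min_size`` genes (default 10) are the unit of
all downstream analysis; smaller ones are unlikely to represent coherent
biological functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mi_network import WeightedNetwork

_CONV_TOL = 1e-10  # bits; stop when a full optimization pass gains less


@dataclass
class Partition:
    """Hard assignment of every network gene to one community."""

    membership: dict  # gene -> community id (int)
    phenotype: str = ""

    @property
    def communities(self) -> dict:
        out: dict = {}
        for gene, cid in self.membership.items():
            out.setdefault(cid, set()).add(gene)
        return out

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.membership.items()), columns=["gene", "community"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, phenotype: str = "") -> "Partition":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        return cls(dict(zip(df["gene"], df["community"])), phenotype)


@dataclass
class Community:
    """A filtered community: phenotype-qualified label, genes, induced edges."""

    label: str
    genes: frozenset
    edges: frozenset  # canonical (a, b) tuples, a < b


@dataclass
class CommunitySet:
    """Communities of one network that passed the minimum-size filter."""

    communities: list  # of Community
    phenotype: str = ""
    min_size: int = 10

    def __iter__(self):
        return iter(self.communities)

    def __len__(self):
        return len(self.communities)

    def by_label(self) -> dict:
        return {c.label: c for c in self.communities}

    def to_tsv(self, path) -> None:
        rows = [
            (c.label, gene)
            for c in self.communities
            for gene in sorted(c.genes)
        ]
        pd.DataFrame(rows, columns=["community", "gene"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# map equation
# ---------------------------------------------------------------------------


def _plogp(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def _flow_arrays(network: WeightedNetwork):
    """Node index map, visit rates p (strength/total), and normalized
    adjacency (edge weight / 2W) as index arrays."""
    nodes = network.nodes
    idx = {g: i for i, g in enumerate(nodes)}
    a = network.edges["gene_a"].map(idx).to_numpy()
    b = network.edges["gene_b"].map(idx).to_numpy()
    w = network.edges["mi"].to_numpy(dtype=float)
    if (w < 0).any():
        raise ValueError("edge weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("network has no positive edge weight")
    strength = np.zeros(len(nodes))
    np.add.at(strength, a, w)
    np.add.at(strength, b, w)
    return nodes, idx, strength / (2 * total), a, b, w / (2 * total)


def map_equation_codelength(network: WeightedNetwork, partition: Partition) -> float:
    """Two-level map-equation codelength of a partition, in bits.

    L = q H(Q) + sum_i p_i^circ H(P_i): the index-codebook term weighted by
    the total module-exit rate plus each module codebook's entropy weighted
    by its total visit (internal + exit) rate.  A single-module partition
    reduces to the entropy of the node visit rates.
    """
    nodes, idx, p, a, b, wr = _flow_arrays(network)
    try:
        mod = np.array([partition.membership[g] for g in nodes])
    except KeyError as e:
        raise ValueError(f"partition does not cover node {e}") from None
    cids, mod = np.unique(mod, return_inverse=True)
    n_mod = len(cids)
    for m in range(n_mod):
        if not np.any(mod == m):
            raise ValueError("empty module in partition")
    # module exit rates: inter-module edges, both directions
    cross = mod[a] != mod[b]
    q = np.zeros(n_mod)
    np.add.at(q, mod[a[cross]], wr[cross])
    np.add.at(q, mod[b[cross]], wr[cross])
    sum_p = np.zeros(n_mod)
    np.add.at(sum_p, mod, p)
    qt = q.sum()
    return float(
        _plogp([qt]).sum()
        - 2 * _plogp(q).sum()
        + _plogp(q + sum_p).sum()
        - _plogp(p).sum()
    )


# ---------------------------------------------------------------------------
# greedy optimizer (Louvain-style local moves + aggregation on the map
# objective)
# ---------------------------------------------------------------------------


def _s(x: float) -> float:
    return x * np.log2(x) if x > 0 else 0.0


def _one_level(adj, p, rng):
    """One level of local moves.  adj: list of dicts j->rate (inter-node,
    symmetric); p: visit rate per node.  Returns module labels."""
    n = len(p)
    module = list(range(n))
    k_ext = [sum(d.values()) for d in adj]
    q = {i: k_ext[i] for i in range(n)}
    sum_p = {i: p[i] for i in range(n)}
    members = {i: {i} for i in range(n)}
    q_tot = sum(q.values())
    next_mid = n

    improved_total = 0.0
    while True:
        improvement = 0.0
        order = rng.permutation(n)
        for node in order:
            m = module[node]
            # rates from node into each neighboring module
            w_to: dict = {}
            for nb, w in adj[node].items():
                w_to[module[nb]] = w_to.get(module[nb], 0.0) + w
            w_own = w_to.get(m, 0.0)
            k = k_ext[node]
            q_m_new = q[m] - k + 2 * w_own
            sp_m_new = sum_p[m] - p[node]
            best_gain = 0.0
            best_target = None
            candidates = [c for c in w_to if c != m]
            if len(members[m]) > 1:
                candidates.append(-1)  # fresh singleton module
            for c in candidates:
                if c == -1:
                    q_c, sp_c, w_c = 0.0, 0.0, 0.0
                else:
                    q_c, sp_c, w_c = q[c], sum_p[c], w_to.get(c, 0.0)
                q_c_new = q_c + k - 2 * w_c
                q_tot_new = q_tot + (q_m_new - q[m]) + (q_c_new - q_c)
                delta = (
                    _s(q_tot_new)
                    - _s(q_tot)
                    - 2 * (_s(q_m_new) + _s(q_c_new) - _s(q[m]) - _s(q_c))
                    + _s(q_m_new + sp_m_new)
                    + _s(q_c_new + sp_c + p[node])
                    - _s(q[m] + sum_p[m])
                    - _s(q_c + sp_c)
                )
                if delta < best_gain - 1e-15:
                    best_gain = delta
                    best_target = c
            if best_target is None:
                continue
            c = best_target
            if c == -1:
                c = next_mid
                next_mid += 1
                q[c] = 0.0
                sum_p[c] = 0.0
                members[c] = set()
                w_c = 0.0
            else:
                w_c = w_to.get(c, 0.0)
            q_tot += (q_m_new - q[m]) + (k - 2 * w_c)
            q[m] = q_m_new
            sum_p[m] = sp_m_new
            members[m].discard(node)
            q[c] = q[c] + k - 2 * w_c
            sum_p[c] += p[node]
            members[c].add(node)
            module[node] = c
            if not members[m]:
                del q[m], sum_p[m], members[m]
            improvement += -best_gain
        improved_total += improvement
        if improvement < _CONV_TOL:
            break
    return np.asarray(module), improved_total


def _aggregate(adj, p, module):
    """Collapse modules into super-nodes; inter-module rates summed."""
    labels = {m: i for i, m in enumerate(sorted(set(module)))}
    m_of = np.array([labels[m] for m in module])
    n_new = len(labels)
    p_new = np.zeros(n_new)
    for node, pi in enumerate(p):
        p_new[m_of[node]] += pi
    adj_new = [dict() for _ in range(n_new)]
    for i, d in enumerate(adj):
        mi_ = m_of[i]
        for j, w in d.items():
            mj = m_of[j]
            if mi_ != mj:
                adj_new[mi_][mj] = adj_new[mi_].get(mj, 0.0) + w
    return adj_new, p_new, m_of


def detect_communities(
    network: WeightedNetwork, seed: int = 0, n_trials: int = 10
) -> Partition:
    """Greedy two-level map-equation minimization with seeded restarts.

    Each trial runs local single-node moves to convergence, aggregates
    modules into super-nodes, and repeats until no pass improves the
    codelength by more than 1e-10 bits.  The best partition over
    ``n_trials`` restarts is returned; accepted moves never increase the
    codelength, and the result is reproducible from the seed.

    Disconnected components can never share a module (merging components
    only adds index-codebook cost), so they are handled natively.
    """
    nodes, idx, p, a, b, wr = _flow_arrays(network)
    n = len(nodes)
    base_adj = [dict() for _ in range(n)]
    for i, j, w in zip(a, b, wr):
        base_adj[i][j] = base_adj[i].get(j, 0.0) + w
        base_adj[j][i] = base_adj[j].get(i, 0.0) + w

    master = np.random.default_rng(seed)
    best_labels = None
    best_len = np.inf
    for _ in range(max(1, n_trials)):
        rng = np.random.default_rng(master.integers(2**31))
        adj, pp = base_adj, p
        assign = np.arange(n)  # original node -> current super-node
        while True:
            module, gain = _one_level(adj, pp, rng)
            if len(set(module.tolist())) == len(pp) or gain < _CONV_TOL:
                # also accept the level's relabeling before stopping
                adj, pp, m_of = _aggregate(adj, pp, module)
                assign = m_of[assign]
                break
            adj, pp, m_of = _aggregate(adj, pp, module)
            assign = m_of[assign]
        part = Partition(
            {nodes[i]: int(assign[i]) for i in range(n)}, network.phenotype
        )
        length = map_equation_codelength(network, part)
        if length < best_len - 1e-12:
            best_len = length
            best_labels = part
    return best_labels


# ---------------------------------------------------------------------------
# partition quality and filtering
# ---------------------------------------------------------------------------


def modularity(network: WeightedNetwork, partition: Partition) -> float:
    """Newman-Girvan modularity Q = sum_i (e_ii - a_i^2) on the weighted
    undirected graph: within-module weight fraction minus the squared
    module strength fraction."""
    nodes, idx, p, a, b, wr = _flow_arrays(network)
    mod = np.array([partition.membership[g] for g in nodes])
    cids, mod = np.unique(mod, return_inverse=True)
    # wr sums to 1/2 over edges; within-module fraction e_ii uses weight/W
    internal = np.zeros(len(cids))
    same = mod[a] == mod[b]
    np.add.at(internal, mod[a[same]], 2 * wr[same])  # w/W per edge
    strength_frac = np.zeros(len(cids))
    np.add.at(strength_frac, mod, p)  # a_i = module strength / 2W
    return float(np.sum(internal - strength_frac**2))


def filter_communities(
    partition: Partition,
    network: WeightedNetwork,
    min_size: int = 10,
    phenotype: str | None = None,
) -> CommunitySet:
    """Keep communities with >= min_size genes, attach induced edge sets,
    and assign phenotype-qualified labels.

    Communities are numbered by decreasing size, ties broken by the
    lexicographically smallest member gene, so labels are stable across
    runs with the same seed (tool-assigned numbers of other software are
    not expected to match).
    """
    phenotype = phenotype if phenotype is not None else partition.phenotype
    comms = [c for c in partition.communities.values() if len(c) >= min_size]
    comms.sort(key=lambda s: (-len(s), min(s)))
    edges_by_gene: dict = {}
    for ea, eb in zip(network.edges["gene_a"], network.edges["gene_b"]):
        edges_by_gene.setdefault(ea, []).append((ea, eb))
        edges_by_gene.setdefault(eb, []).append((ea, eb))
    out = []
    for num, genes in enumerate(comms, start=1):
        induced = {
            e
            for g in genes
            for e in edges_by_gene.get(g, ())
            if e[0] in genes and e[1] in genes
        }
        label = f"{phenotype} {num}" if phenotype else str(num)
        out.append(Community(label, frozenset(genes), frozenset(induced)))
    return CommunitySet(out, phenotype or "", min_size)


def network_summary(
    network: WeightedNetwork,
    partition: Partition,
    community_set: CommunitySet,
    ora_results: pd.DataFrame | None = None,
    alpha: float = 0.05,
    selected_labels: set | None = None,
) -> dict:
    """Per-network metric vector: gene count, modularity, community counts,
    and (when enrichment results are supplied) enriched / selected
    community counts."""
    summary = {
        "phenotype": network.phenotype,
        "n_genes": len(network.nodes),
        "n_edges": network.n_edges,
        "modularity": modularity(network, partition),
        "total_communities": partition.n_communities,
        "communities_min_size": len(community_set),
    }
    if ora_results is not None and len(ora_results):
        sig = ora_results[ora_results["q_value"] < alpha]
        summary["enriched_communities"] = sig["community"].nunique()
    elif ora_results is not None:
        summary["enriched_communities"] = 0
    if selected_labels is not None:
        own = {c.label for c in community_set}
        summary["selected_communities"] = len(own & selected_labels)
    return summary
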