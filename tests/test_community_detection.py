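import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from coexnet.community_detection import (
    Partition,
    detect_communities,
    filter_communities,
    map_equation_codelength,
    modularity,
    network_summary,
)

from conftest import (
    clique,
    make_network,
    planted_partition_network,
    random_weighted_network,
)


def naive_codelength(network, partition):
    """Direct evaluation of L = q H(Q) + sum_i p_i H(P_i) from the
    definition, independent of the production implementation."""
    g = network.to_networkx()
    two_w = 2 * sum(d["weight"] for _, _, d in g.edges(data=True))
    p = {v: g.degree(v, weight="weight") / two_w for v in g}
    modules = {}
    for v in g:
        modules.setdefault(partition.membership[v], set()).add(v)
    q = {}
    for m, nodes in modules.items():
        q[m] = (
            sum(
                d["weight"]
                for a, b, d in g.edges(data=True)
                if (a in nodes) != (b in nodes)
            )
            / two_w
        )
    q_tot = sum(q.values())

    def entropy(probs):
        probs = [x for x in probs if x > 0]
        return -sum(x * np.log2(x) for x in probs)

    index_term = 0.0
    if q_tot > 0:
        index_term = q_tot * entropy([q[m] / q_tot for m in modules])
    module_term = 0.0
    for m, nodes in modules.items():
        tot = q[m] + sum(p[v] for v in nodes)
        if tot > 0:
            module_term += tot * entropy(
                [q[m] / tot] + [p[v] / tot for v in nodes]
            )
    return index_term + module_term


def naive_modularity(network, partition):
    g = network.to_networkx()
    two_w = 2 * sum(d["weight"] for _, _, d in g.edges(data=True))
    q = 0.0
    for a in g:
        for b in g:
            if partition.membership[a] != partition.membership[b]:
                continue
            w = g[a][b]["weight"] if g.has_edge(a, b) else 0.0
            ka = g.degree(a, weight="weight")
            kb = g.degree(b, weight="weight")
            q += w / two_w - ka * kb / two_w**2
    return q


class TestCodelength:
    def test_four_cycle_single_module_is_two_bits(self):
        net = make_network([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        part = Partition({g: 0 for g in "abcd"})
        assert map_equation_codelength(net, part) == pytest.approx(2.0)

    def test_two_triangles_two_modules_is_log2_3(self, two_triangles):
        part = Partition(
            {"a0": 0, "a1": 0, "a2": 0, "b0": 1, "b1": 1, "b2": 1}
        )
        assert map_equation_codelength(two_triangles, part) == pytest.approx(
            np.log2(3)
        )

    def test_matches_naive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(4, 16))
            net = random_weighted_network(n, 0.4, rng)
            nodes = net.nodes
            for _ in range(3):
                labels = rng.integers(0, max(2, n // 3), size=len(nodes))
                part = Partition(dict(zip(nodes, labels.tolist())))
                assert map_equation_codelength(net, part) == pytest.approx(
                    naive_codelength(net, part), abs=1e-12
                )

    def test_incomplete_partition_rejected(self, two_triangles):
        with pytest.raises(ValueError):
            map_equation_codelength(two_triangles, Partition({"a0": 0}))


class TestDetection:
    def test_disjoint_cliques_are_separate_communities(self):
        net = make_network(clique("a", 5) + clique("b", 5))
        part = detect_communities(net, seed=1, n_trials=5)
        sizes = sorted(len(c) for c in part.communities.values())
        assert sizes == [5, 5]
        # the two cliques never share a module
        assert len({part.membership[f"a{i}"] for i in range(5)}) == 1
        assert len({part.membership[f"b{i}"] for i in range(5)}) == 1

    def test_beats_trivial_partitions(self):
        rng = np.random.default_rng(23)
        net = random_weighted_network(12, 0.35, rng)
        part = detect_communities(net, seed=2, n_trials=5)
        length = map_equation_codelength(net, part)
        nodes = net.nodes
        one = map_equation_codelength(net, Partition({v: 0 for v in nodes}))
        singles = map_equation_codelength(
            net, Partition({v: i for i, v in enumerate(nodes)})
        )
        assert length <= one + 1e-12
        assert length <= singles + 1e-12

    def test_planted_partition_fully_recovered(self):
        rng = np.random.default_rng(29)
        net = planted_partition_network(rng)
        part = detect_communities(net, seed=5, n_trials=10)
        nodes = net.nodes
        truth = [int(v[1:]) // 25 for v in nodes]
        pred = [part.membership[v] for v in nodes]
        assert normalized_mutual_info_score(truth, pred) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(31)
        net = random_weighted_network(30, 0.2, rng)
        a = detect_communities(net, seed=7, n_trials=5)
        b = detect_communities(net, seed=7, n_trials=5)
        assert a.membership == b.membership


class TestModularity:
    def test_two_cliques_correct_split_is_half(self):
        net = make_network(clique("a", 4) + clique("b", 4))
        part = Partition(
            {f"a{i}": 0 for i in range(4)} | {f"b{i}": 1 for i in range(4)}
        )
        assert modularity(net, part) == pytest.approx(0.5)

    def test_single_module_is_zero(self):
        rng = np.random.default_rng(37)
        net = random_weighted_network(10, 0.4, rng)
        part = Partition({v: 0 for v in net.nodes})
        assert modularity(net, part) == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_double_sum_and_networkx(self):
        rng = np.random.default_rng(41)
        for _ in range(5):
            net = random_weighted_network(12, 0.4, rng)
            nodes = net.nodes
            labels = rng.integers(0, 3, size=len(nodes))
            part = Partition(dict(zip(nodes, labels.tolist())))
            ours = modularity(net, part)
            assert ours == pytest.approx(naive_modularity(net, part), abs=1e-12)
            groups = {}
            for v, m in part.membership.items():
                groups.setdefault(m, set()).add(v)
            ref = nx.community.modularity(
                net.to_networkx(), groups.values(), weight="weight"
            )
            assert ours == pytest.approx(ref, abs=1e-12)


class TestFilteringAndSummary:
    def _partition_of_sizes(self, sizes):
        rows = []
        membership = {}
        gid = 0
        for cid, size in enumerate(sizes):
            genes = [f"g{gid + i:03d}" for i in range(size)]
            gid += size
            for g in genes:
                membership[g] = cid
            rows += [(a, b) for a, b in itertools.combinations(genes, 2)]
        return make_network(rows), Partition(membership)

    def test_min_size_filter(self):
        net, part = self._partition_of_sizes([12, 9, 30])
        cset = filter_communities(part, net, min_size=10, phenotype="P")
        assert len(cset) == 2
        assert [c.label for c in cset] == ["P 1", "P 2"]  # by decreasing size
        assert [len(c.genes) for c in cset] == [30, 12]

    def test_min_size_one_keeps_all(self):
        net, part = self._partition_of_sizes([3, 4, 5])
        assert len(filter_communities(part, net, min_size=1)) == 3

    def test_induced_edges_are_within_community(self):
        net, part = self._partition_of_sizes([10, 11])
        cset = filter_communities(part, net, min_size=10, phenotype="P")
        for c in cset:
            assert all(a in c.genes and b in c.genes for a, b in c.edges)
        sizes = {len(c.genes): len(c.edges) for c in cset}
        assert sizes == {10: 45, 11: 55}  # full cliques

    def test_summary_two_small_cliques(self):
        net = make_network(clique("a", 5) + clique("b", 5))
        part = detect_communities(net, seed=1, n_trials=3)
        cset = filter_communities(part, net, min_size=10, phenotype="X")
        s = network_summary(net, part, cset)
        assert s["n_genes"] == 10
        assert s["total_communities"] == 2
        assert s["communities_min_size"] == 0
        assert s["modularity"] == pytest.approx(modularity(net, part))
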