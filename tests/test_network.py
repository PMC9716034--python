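"""Correlation screening, network construction and Louvain community tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

import networkx as nx
from conftest import make_study
from idegnet.network import (CoexprNetwork, build_network, filter_modules,
                             graph_density, louvain_partition, modularity,
                             module_densities, pearson_with_p,
                             select_related_genes)


def _net_from_edges(edge_list, nodes=None):
    edges = pd.DataFrame(edge_list, columns=["gene_a", "gene_b", "weight"])
    edges["r"] = edges["weight"]
    edges["p"] = 0.0
    if nodes is None:
        nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    return CoexprNetwork(nodes=list(nodes), edges=edges)


def _exhaustive_best_q(net):
    """Max modularity over all partitions (tiny graphs only)."""
    nodes = net.nonisolated()
    adj = {v: dict(net.adjacency()[v]) for v in nodes}

    def partitions(seq):
        if not seq:
            yield []
            return
        head, *rest = seq
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1:]
            yield part + [[head]]

    best = -np.inf
    for part in partitions(nodes):
        mapping = {v: i for i, block in enumerate(part) for v in block}
        best = max(best, modularity(adj, mapping))
    return best


class TestPearson:
    def test_perfect_linearity(self):
        st = make_study([[1, 2, 3], [2, 4, 6]], ["case", "control", "case"])
        tab = pearson_with_p(st, ["g1"], ["g2"])
        assert tab["r"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_r_and_p(self):
        """x=(1,2,3,4), y=(2,1,4,3): r=0.6, t=1.061 on 2 df, p~0.40."""
        st = make_study([[1, 2, 3, 4], [2, 1, 4, 3]],
                        ["case", "control"] * 2)
        tab = pearson_with_p(st, ["g1"], ["g2"])
        assert tab["r"].iloc[0] == pytest.approx(0.6)
        assert tab["p"].iloc[0] == pytest.approx(0.40, abs=0.01)

    def test_scale_invariance(self, rng):
        vals = rng.standard_normal((4, 10))
        st1 = make_study(vals, ["case", "control"] * 5)
        standardized = (vals - vals.mean(1, keepdims=True)) / vals.std(
            1, keepdims=True
        )
        st2 = make_study(standardized, ["case", "control"] * 5)
        t1 = pearson_with_p(st1, ["g1", "g2"], ["g3", "g4"])
        t2 = pearson_with_p(st2, ["g1", "g2"], ["g3", "g4"])
        np.testing.assert_allclose(t1["r"], t2["r"], atol=1e-12)

    def test_matches_scipy_oracle(self, rng):
        from scipy.stats import pearsonr
        vals = rng.standard_normal((6, 15))
        st = make_study(vals, ["case", "control"] * 7 + ["case"])
        tab = pearson_with_p(st, ["g1", "g2", "g3"], ["g4", "g5", "g6"])
        for _, row in tab.iterrows():
            i = int(row.gene_a[1:]) - 1
            j = int(row.gene_b[1:]) - 1
            r, p = pearsonr(vals[i], vals[j])
            assert row.r == pytest.approx(r, abs=1e-10)
            assert row.p == pytest.approx(p, abs=1e-10)

    def test_self_pairs_excluded(self, rng):
        vals = rng.standard_normal((3, 6))
        st = make_study(vals, ["case", "control"] * 3)
        tab = pearson_with_p(st, ["g1", "g2"], ["g2", "g3"])
        assert not ((tab.gene_a == tab.gene_b).any())


class TestRelatedGeneSelection:
    def test_threshold_boundaries(self):
        cors = pd.DataFrame({
            "gene_a": ["i1"] * 4,
            "gene_b": ["a", "b", "c", "d"],
            "r": [0.45, 0.39, -0.45, 0.41],
            "p": [0.01, 0.01, 0.01, 0.20],
            "n": 30,
        })
        assert select_related_genes(cors) == {"a", "c"}

    def test_brute_force_oracle(self, rng):
        cors = pd.DataFrame({
            "gene_a": [f"i{k}" for k in range(20)],
            "gene_b": [f"g{k}" for k in range(20)],
            "r": rng.uniform(-1, 1, 20),
            "p": rng.uniform(0, 0.2, 20),
            "n": 30,
        })
        oracle = {
            row.gene_b for row in cors.itertuples()
            if abs(row.r) > 0.40 and row.p < 0.05
        }
        assert select_related_genes(cors) == oracle


class TestBuildNetwork:
    def test_one_factor_triangle(self):
        f = np.array([0.3, -1.2, 0.8, 1.5, -0.6])
        st = make_study(np.stack([f, 2 * f, -f]),
                        ["case", "control"] * 2 + ["case"])
        net = build_network(st, ["g1", "g2", "g3"])
        assert len(net.edges) == 3
        np.testing.assert_allclose(net.edges["weight"], 1.0, atol=1e-10)

    def test_null_genes_make_no_edges(self, rng):
        vals = rng.standard_normal((30, 100))
        st = make_study(vals, ["case", "control"] * 50)
        with pytest.warns(UserWarning, match="no edges"):
            net = build_network(st, [f"g{i + 1}" for i in range(30)])
        assert net.edges.empty

    def test_boundary_r_is_excluded(self):
        edges = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"],
                              "r": [0.70], "p": [0.001]})
        keep = (edges["r"].abs() > 0.70) & (edges["p"] < 0.05)
        assert not keep.any()


class TestLouvain:
    def test_two_disconnected_triangles(self):
        tri1 = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)]
        tri2 = [("d", "e", 1.0), ("e", "f", 1.0), ("d", "f", 1.0)]
        net = _net_from_edges(tri1 + tri2)
        part = louvain_partition(net, seed=1)
        mods = part.modules()
        assert sorted(map(sorted, mods.values())) == [list("abc"), list("def")]
        assert part.modularity == pytest.approx(0.5)

    def test_bridged_triangles(self):
        """Two 3-cliques + one bridge: Q = 6/7 - 1/2 ~ 0.357."""
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
                 ("d", "e", 1.0), ("e", "f", 1.0), ("d", "f", 1.0),
                 ("c", "d", 1.0)]
        net = _net_from_edges(edges)
        part = louvain_partition(net, seed=1)
        assert part.modularity == pytest.approx(6 / 7 - 0.5, abs=1e-9)
        assert part.modularity == pytest.approx(_exhaustive_best_q(net))

    def test_matches_exhaustive_optimum_on_random_graphs(self, rng):
        for trial in range(15):
            n = int(rng.integers(4, 8))
            edges = []
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.5:
                    edges.append((f"n{i}", f"n{j}",
                                  float(rng.uniform(0.2, 1.0))))
            if not edges:
                continue
            net = _net_from_edges(edges)
            part = louvain_partition(net, seed=trial)
            assert part.modularity == pytest.approx(
                _exhaustive_best_q(net), abs=1e-9
            ), f"trial {trial}"

    def test_q_agrees_with_networkx(self, rng):
        edges = [(f"n{i}", f"n{j}", float(rng.uniform(0.1, 1)))
                 for i, j in itertools.combinations(range(10), 2)
                 if rng.random() < 0.4]
        net = _net_from_edges(edges)
        part = louvain_partition(net, seed=0)
        g = nx.Graph()
        for a, b, w in edges:
            g.add_edge(a, b, weight=w)
        comms = {}
        for v, m in part.assignment.items():
            if m:
                comms.setdefault(m, set()).add(v)
        q_nx = nx.community.modularity(g, list(comms.values()), weight="weight")
        assert part.modularity == pytest.approx(q_nx, abs=1e-10)

    def test_planted_partition_recovery(self, rng):
        from sklearn.metrics import adjusted_rand_score
        blocks, size = 4, 50
        edges = []
        labels = {}
        for b in range(blocks):
            for i in range(size):
                labels[f"n{b}_{i}"] = b
        nodes = list(labels)
        for u, v in itertools.combinations(nodes, 2):
            p = 0.3 if labels[u] == labels[v] else 0.01
            if rng.random() < p:
                edges.append((u, v, 1.0))
        net = _net_from_edges(edges, nodes=nodes)
        part = louvain_partition(net, seed=3)
        found = [part.assignment[v] for v in nodes]
        truth = [labels[v] for v in nodes]
        assert adjusted_rand_score(truth, found) >= 0.9

    def test_deterministic_under_seed(self, rng):
        edges = [(f"n{i}", f"n{j}", float(rng.uniform(0.1, 1)))
                 for i, j in itertools.combinations(range(12), 2)
                 if rng.random() < 0.3]
        net = _net_from_edges(edges)
        p1 = louvain_partition(net, seed=5)
        p2 = louvain_partition(net, seed=5)
        assert p1.assignment == p2.assignment

    def test_edgeless_network_raises(self):
        net = CoexprNetwork(nodes=["a", "b"], edges=pd.DataFrame(
            columns=["gene_a", "gene_b", "r", "p", "weight"]))
        with pytest.raises(ValueError, match="edgeless"):
            louvain_partition(net)


class TestFilterAndDensity:
    @staticmethod
    def _partition(sizes):
        assignment = {}
        i = 0
        for m, s in sizes.items():
            for _ in range(s):
                assignment[f"g{i}"] = m
                i += 1
        from idegnet.network import ModulePartition
        return ModulePartition(assignment=assignment, modularity=0.4, seed=0)

    def test_below_30_deleted_30_kept(self):
        part = self._partition({"M1": 29, "M2": 30})
        out = filter_modules(part, min_size=30)
        assert set(out.modules()) == {"M2"}

    def test_min_size_one_is_identity(self):
        part = self._partition({"M1": 3, "M2": 1})
        out = filter_modules(part, min_size=1)
        assert out.assignment == part.assignment

    def test_toy_partition_counts(self):
        part = self._partition({"M1": 40, "M2": 35, "M3": 10})
        out = filter_modules(part, min_size=30)
        assert sorted(out.sizes.values()) == [35, 40]

    def test_triangle_density_is_one(self):
        net = _net_from_edges([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        assert graph_density(net) == pytest.approx(1.0)

    def test_path_density(self):
        net = _net_from_edges([("a", "b", 1), ("b", "c", 1)])
        assert graph_density(net) == pytest.approx(2 / 3)

    def test_density_matches_counting_oracle(self, rng):
        nodes = [f"n{i}" for i in range(10)]
        edges = [(a, b, 1.0) for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.4]
        net = _net_from_edges(edges, nodes=nodes)
        subset = nodes[:6]
        count = sum(1 for a, b, _ in edges if a in subset and b in subset)
        assert graph_density(net, subset) == pytest.approx(
            2 * count / (6 * 5)
        )

    def test_singleton_subset_raises(self):
        net = _net_from_edges([("a", "b", 1)])
        with pytest.raises(ValueError):
            graph_density(net, ["a"])


def test_module_density_exceeds_network_density_on_planted_data():
    """Planted-community networks: module density > whole-network density."""
    from idegnet import StudyConfig, generate_study
    cfg = StudyConfig(n_genes=400, module_sizes=(40, 40, 40), loading=2.0,
                      batch_sizes=((20, 20),), effect=0.0, coupling=0.0)
    studies, truth = generate_study(cfg, seed=9)
    st = studies["disease1"]
    members = [g for gs in truth.modules["disease1"].values() for g in gs]
    net = build_network(st, members)
    part = filter_modules(louvain_partition(net, seed=1), min_size=30)
    dens = module_densities(net, part)
    assert dens, "expected surviving modules"
    whole = graph_density(net, net.nonisolated())
    assert all(d >= whole for d in dens.values())
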