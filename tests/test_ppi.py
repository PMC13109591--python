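import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from dopasig.enrichment import RankedList
from dopasig.ppi import build_seeded_network, expand_network, mcl, validate_modules_gsea
from dopasig.simulate import simulate_ppi


def _edges(rows):
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


class TestSeededNetwork:
    def test_isolated_seeds_kept(self):
        edges = _edges([("x", "y", 900)])
        g = build_seeded_network(edges, ["x", "a"], 400)
        assert set(g.nodes) >= {"x", "a"}
        assert g.number_of_edges() == 0  # y is not a seed

    def test_no_seed_in_edges_errors(self):
        with pytest.raises(ValueError, match="seed"):
            build_seeded_network(_edges([("x", "y", 500)]), ["a", "b"], 400)

    def test_induced_edges_match_brute_force(self):
        rows = [("a", "b", 450), ("a", "c", 300), ("b", "c", 700),
                ("c", "d", 800), ("d", "e", 950), ("e", "f", 350)]
        seeds = ["a", "b", "c", "d"]
        g = build_seeded_network(_edges(rows), seeds, 400)
        expected = {(u, v) for u, v, s in rows
                    if s >= 400 and u in seeds and v in seeds}
        assert {tuple(sorted(e)) for e in g.edges} == {tuple(sorted(e)) for e in expected}

    def test_raising_threshold_never_adds_edges(self):
        rows = [("a", "b", 450), ("b", "c", 700), ("c", "a", 500)]
        low = build_seeded_network(_edges(rows), ["a", "b", "c"], 400)
        high = build_seeded_network(_edges(rows), ["a", "b", "c"], 700)
        assert set(high.edges) <= set(low.edges)


class TestExpand:
    def test_max_added_zero_noop(self):
        edges = _edges([("a", "b", 500), ("b", "c", 600)])
        core = build_seeded_network(edges, ["a"], 400)
        out = expand_network(core, edges, order=2, max_added=0)
        assert set(out.nodes) == set(core.nodes)

    def test_star_leaf_gains_hub(self):
        edges = _edges([("hub", f"leaf{i}", 800) for i in range(4)])
        core = build_seeded_network(edges, ["leaf0"], 400)
        out = expand_network(core, edges, order=1, max_added=10)
        assert "hub" in out.nodes

    def test_unlimited_expansion_equals_bfs_depth2(self, rng):
        nodes = [f"n{i}" for i in range(30)]
        rows = []
        for i in range(30):
            for j in range(i + 1, 30):
                if rng.random() < 0.1:
                    rows.append((nodes[i], nodes[j], int(rng.integers(400, 1000))))
        edges = _edges(rows)
        g_full = nx.from_pandas_edgelist(edges, "node1", "node2")
        seed_nodes = [n for n in nodes[:3] if n in g_full]
        if not seed_nodes:
            pytest.skip("random draw left no seed in graph")
        core = build_seeded_network(edges, seed_nodes, 400)
        out = expand_network(core, edges, order=2, max_added=None)
        bfs = set(seed_nodes)
        for _ in range(2):
            nxt = set(bfs)
            for n in bfs:
                if n in g_full:
                    nxt |= set(g_full.neighbors(n))
            bfs = nxt
        assert set(out.nodes) == bfs

    def test_expansion_prefix_monotone(self):
        edges = _edges([("s", f"x{i}", 500 + 10 * i) for i in range(6)]
                       + [(f"x{i}", f"x{j}", 450) for i in range(6) for j in range(i + 1, 6)])
        core = build_seeded_network(edges, ["s"], 400)
        prev = None
        for k in range(0, 5):
            out = expand_network(core, edges, order=1, max_added=k)
            nodes = set(out.nodes) - {"s"}
            if prev is not None:
                assert prev <= nodes
            prev = nodes


class TestMcl:
    def test_two_disjoint_triangles(self):
        edges = _edges([("a", "b", 900), ("b", "c", 900), ("a", "c", 900),
                        ("x", "y", 900), ("y", "z", 900), ("x", "z", 900)])
        g = build_seeded_network(edges, ["a", "b", "c", "x", "y", "z"], 400)
        part = mcl(g)
        sets = {frozenset(m) for m in part.modules.values()}
        assert sets == {frozenset("abc"), frozenset("xyz")}

    def test_barbell_splits_at_bridge(self):
        g = nx.Graph()
        left = [f"l{i}" for i in range(5)]
        right = [f"r{i}" for i in range(5)]
        for grp in (left, right):
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(grp[i], grp[j], weight=0.9)
        g.add_edge("l0", "r0", weight=0.9)
        part = mcl(g, inflation=2.0)
        sets = {frozenset(m) for m in part.modules.values()}
        assert sets == {frozenset(left), frozenset(right)}

    def test_planted_partition_recovery(self):
        aris = []
        for seed in range(10):
            edges, truth = simulate_ppi(60, 3, 0.4, 0.02, seed=seed)
            g = nx.Graph()
            for r in edges.itertuples():
                g.add_edge(r.node1, r.node2, weight=r.combined_score / 1000.0)
            part = mcl(g)
            labels_true, labels_pred = [], []
            truth_label = {n: m for m, ns in truth.modules.items() for n in ns}
            pred_label = part.labels()
            for n in g.nodes:
                labels_true.append(truth_label[n])
                labels_pred.append(pred_label[n])
            aris.append(adjusted_rand_score(labels_true, labels_pred))
        assert np.mean(aris) > 0.9

    def test_column_sums_stay_stochastic(self):
        # re-run one inflation step manually to assert normalization
        edges, _ = simulate_ppi(20, 2, 0.5, 0.1, seed=1)
        g = nx.Graph()
        for r in edges.itertuples():
            g.add_edge(r.node1, r.node2, weight=r.combined_score / 1000.0)
        nodes = sorted(g.nodes)
        n = len(nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        m = np.zeros((n, n))
        for a, b, d in g.edges(data=True):
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = d["weight"]
        np.fill_diagonal(m, m.max(axis=0))
        m /= m.sum(axis=0, keepdims=True)
        for _ in range(5):
            m = (m @ m) ** 2.0
            m /= m.sum(axis=0, keepdims=True)
            np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-9)

    def test_deterministic(self):
        edges, _ = simulate_ppi(30, 2, 0.5, 0.05, seed=3)
        g = nx.Graph()
        for r in edges.itertuples():
            g.add_edge(r.node1, r.node2, weight=r.combined_score / 1000.0)
        p1, p2 = mcl(g), mcl(g)
        assert p1.modules == p2.modules

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mcl(nx.Graph())


class TestValidateModules:
    def test_planted_module_enriched_random_not(self, rng):
        n = 200
        scores = np.sort(rng.normal(0, 3, n))[::-1]
        ranked = RankedList([f"g{i}" for i in range(n)], scores)
        from dopasig.ppi import ModulePartition
        part = ModulePartition(modules={
            "top": [f"g{i}" for i in range(12)],
            "rand": [f"g{i}" for i in rng.choice(n, 12, replace=False)],
        })
        res = validate_modules_gsea(part, {"c1": ranked}, n_perm=300, seed=4)
        top = res.set_index("set").loc["top"]
        assert top["nes"] > 0 and top["fdr"] < 0.05

    def test_module_outside_universe_skipped(self, rng):
        ranked = RankedList(["a", "b", "c", "d", "e", "f", "g", "h"],
                            np.arange(8, 0, -1.0))
        from dopasig.ppi import ModulePartition
        part = ModulePartition(modules={"ghost": ["q1", "q2", "q3", "q4", "q5"]})
        with pytest.warns(UserWarning, match="empty"):
            res = validate_modules_gsea(part, {"c": ranked}, n_perm=20, seed=0)
        assert len(res) == 0
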