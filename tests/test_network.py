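import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cohortsom import network as net
from cohortsom.errors import ValidationError


def _graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return net.CorrelationNetwork(graph=g)


def spanning_tree_oracle(graph: nx.Graph) -> float:
    """Max total |weight| over all spanning trees, by exhaustive enumeration."""
    edges = list(graph.edges(data="weight"))
    n = graph.number_of_nodes()
    best = -np.inf
    for subset in itertools.combinations(edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        g.add_weighted_edges_from(subset)
        if nx.is_connected(g):
            best = max(best, sum(abs(w) for _, _, w in subset))
    return best


def partitions(items):
    """All set partitions of a list."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


class TestSexWeightedSpearman:
    def test_single_sex_is_plain_spearman(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=list("abc"))
        sex = np.array(["female"] * 30)
        cn = net.sex_weighted_spearman(df, sex)
        for u, v in itertools.combinations("abc", 2):
            expected = sps.spearmanr(df[u], df[v]).statistic
            assert cn.graph[u][v]["weight"] == pytest.approx(expected)

    def test_weighted_average_formula(self):
        # exact constructed case: rho_f = 0.5 (n=5), rho_m = 0.0 (n=5)
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y_f = [2.0, 4.0, 1.0, 3.0, 5.0]   # sum d^2 = 10 -> rho 0.5
        y_m = [2.0, 5.0, 3.0, 1.0, 4.0]   # sum d^2 = 20 -> rho 0.0
        df = pd.DataFrame({"x": x + x, "y": y_f + y_m})
        sex = np.array(["female"] * 5 + ["male"] * 5)
        cn = net.sex_weighted_spearman(df, sex)
        assert cn.graph["x"]["y"]["weight"] == pytest.approx(0.25)

    def test_formula_against_scipy_oracle(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, (50, 2)), columns=["a", "b"])
        sex = np.where(rng.random(50) < 0.6, "female", "male")
        cn = net.sex_weighted_spearman(df, sex)
        expected = 0.0
        for level in ("female", "male"):
            mask = sex == level
            rho = sps.spearmanr(df.loc[mask, "a"], df.loc[mask, "b"]).statistic
            expected += mask.mean() * rho
        assert cn.graph["a"]["b"]["weight"] == pytest.approx(expected)

    def test_monotone_copy_weight_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})  # monotone transform
        sex = np.where(np.arange(40) < 24, "female", "male")
        cn = net.sex_weighted_spearman(df, sex)
        assert cn.graph["x"]["y"]["weight"] == pytest.approx(1.0)

    def test_constant_variable_zero_edges_with_warning(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(0, 1, 20),
                           "b": rng.normal(0, 1, 20),
                           "c": np.full(20, 7.0)})
        sex = np.where(np.arange(20) < 10, "female", "male")
        with pytest.warns(UserWarning, match="constant"):
            cn = net.sex_weighted_spearman(df, sex)
        assert cn.graph["a"]["c"]["weight"] == 0.0
        assert cn.graph["b"]["c"]["weight"] == 0.0

    def test_too_few_variables(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValidationError):
            net.sex_weighted_spearman(df, np.array(["female"] * 4))


class TestPruneSpanningTree:
    def test_triangle_drops_weakest(self):
        cn = _graph([("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.1)])
        pruned = net.prune_spanning_tree(cn)
        kept = {(u, v) for u, v, _ in pruned.edges()}
        assert kept == {("a", "b"), ("b", "c")}
        assert pruned.pruned

    def test_tree_unchanged(self):
        cn = _graph([("a", "b", 0.5), ("b", "c", -0.4), ("c", "d", 0.3)])
        pruned = net.prune_spanning_tree(cn)
        assert pruned.edges() == cn.edges()

    def test_matches_enumeration_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.6, seed=seed)
            if not nx.is_connected(g):
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(-1, 1))
            relabeled = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
            cn = net.CorrelationNetwork(graph=relabeled)
            pruned = net.prune_spanning_tree(cn)
            total = sum(abs(w) for _, _, w in pruned.edges())
            assert total == pytest.approx(spanning_tree_oracle(relabeled))
            assert pruned.graph.number_of_edges() == n - 1

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(4)
        edges = [(f"v{i}", f"v{j}", float(rng.uniform(-1, 1)))
                 for i, j in itertools.combinations(range(6), 2)]
        flipped = [(u, v, -w) for u, v, w in edges]
        kept = {(u, v) for u, v, _ in net.prune_spanning_tree(_graph(edges)).edges()}
        kept_flipped = {(u, v) for u, v, _
                        in net.prune_spanning_tree(_graph(flipped)).edges()}
        assert kept == kept_flipped

    def test_multi_component(self):
        cn = _graph([("a", "b", 0.5), ("b", "c", 0.4), ("a", "c", 0.3),
                     ("x", "y", 0.9)])
        pruned = net.prune_spanning_tree(cn)
        # nodes - components = 5 - 2 = 3 edges
        assert pruned.graph.number_of_edges() == 3

    def test_empty_graph(self):
        pruned = net.prune_spanning_tree(
            net.CorrelationNetwork(graph=nx.Graph()))
        assert pruned.graph.number_of_nodes() == 0


class TestDetectModules:
    def test_two_blocks_split_at_weak_edge(self):
        cn = _graph([("a", "b", 0.8), ("b", "c", 0.7),
                     ("d", "e", 0.8), ("e", "f", 0.7),
                     ("c", "d", 0.05)])
        ms = net.detect_modules(cn)
        mods = sorted(map(sorted, ms.modules().values()))
        assert mods == [["a", "b", "c"], ["d", "e", "f"]]

    def test_two_blocks_matches_exhaustive_partition_search(self):
        edges = [("a", "b", 0.8), ("b", "c", 0.7),
                 ("d", "e", 0.8), ("e", "f", 0.7), ("c", "d", 0.05)]
        cn = _graph(edges)
        nodes = sorted(cn.graph.nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        adj = np.zeros((6, 6))
        for u, v, w in edges:
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = abs(w)
        best_q, best_part = -np.inf, None
        for part in partitions(nodes):
            q = net._modularity(adj, [{idx[v] for v in block}
                                      for block in part])
            if q > best_q:
                best_q, best_part = q, part
        ms = net.detect_modules(cn)
        returned = sorted(map(sorted, ms.modules().values()))
        assert returned == sorted(map(sorted, best_part))

    def test_disconnected_nodes_are_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        ms = net.detect_modules(net.CorrelationNetwork(graph=g))
        assert sorted(map(sorted, ms.modules().values())) == [["a"], ["b"], ["c"]]

    def test_singleton_graph(self):
        g = nx.Graph()
        g.add_node("only")
        ms = net.detect_modules(net.CorrelationNetwork(graph=g))
        assert ms.assignment == {"only": 0}

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_chain_matches_exhaustive_merge_oracle(self, n):
        # identical-weight chain: returned modularity equals the best
        # achievable by any agglomerative merge sequence
        labels = [f"v{i}" for i in range(n)]
        edges = [(labels[i], labels[i + 1], 0.5) for i in range(n - 1)]
        cn = _graph(edges)
        ms = net.detect_modules(cn)
        idx = {v: i for i, v in enumerate(labels)}
        adj = np.zeros((n, n))
        for u, v, w in edges:
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = abs(w)
        # exhaustive search over merge sequences
        start = frozenset(frozenset([i]) for i in range(n))
        seen, stack = {start}, [start]
        best = net._modularity(adj, [set(c) for c in start])
        while stack:
            part = stack.pop()
            comms = list(part)
            best = max(best, net._modularity(adj, [set(c) for c in comms]))
            for a, b in itertools.combinations(range(len(comms)), 2):
                ia, ib = sorted(comms[a]), sorted(comms[b])
                if adj[np.ix_(ia, ib)].sum() == 0:
                    continue
                merged = frozenset(
                    [c for k, c in enumerate(comms) if k not in (a, b)]
                    + [comms[a] | comms[b]])
                if merged not in seen:
                    seen.add(merged)
                    stack.append(merged)
        got = net._modularity(
            adj, [{idx[v] for v in block}
                  for block in ms.modules().values()])
        assert got == pytest.approx(best)

    def test_at_least_singleton_modularity(self):
        rng = np.random.default_rng(7)
        nodes = [f"v{i}" for i in range(12)]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in itertools.combinations(nodes, 2):
            if rng.random() < 0.3:
                g.add_edge(u, v, weight=float(rng.uniform(-1, 1)))
        cn = net.CorrelationNetwork(graph=g)
        ms = net.detect_modules(cn)
        idx = {v: i for i, v in enumerate(sorted(g.nodes))}
        adj = np.zeros((12, 12))
        for u, v, d in g.edges(data=True):
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = abs(d["weight"])
        q = net._modularity(adj, [{idx[v] for v in block}
                                  for block in ms.modules().values()])
        q0 = net._modularity(adj, [{i} for i in range(12)])
        assert q >= q0 - 1e-12

    def test_deterministic(self):
        edges = [("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5)]
        first = net.detect_modules(_graph(edges)).assignment
        for _ in range(3):
            assert net.detect_modules(_graph(edges)).assignment == first


class TestModuleScores:
    def _modules(self, mapping):
        return net.ModuleSet(assignment=mapping)

    def test_single_variable_module(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"a": rng.normal(5, 2, 30)})
        ms = net.module_scores(data, self._modules({"a": 0}))
        z = (data["a"] - data["a"].mean()) / data["a"].std(ddof=1)
        assert np.allclose(ms.scores[(0, "pc1")], z)
        assert np.allclose(ms.scores[(0, "pc2")], 0.0)

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 25)
        data = pd.DataFrame({"a": x, "b": 3.0 * x + 1.0})
        ms = net.module_scores(data, self._modules({"a": 0, "b": 0}))
        assert ms.explained_variance[0][0] == pytest.approx(1.0)

    def test_matches_characteristic_polynomial_oracle(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=list("abc"))
        ms = net.module_scores(data, self._modules({"a": 0, "b": 0, "c": 0}))
        z = (data - data.mean()) / data.std(ddof=1)
        corr = z.T @ z / (len(data) - 1)
        r = corr.to_numpy()
        # characteristic polynomial of a 3x3 symmetric matrix
        tr = np.trace(r)
        minors = (r[0, 0] * r[1, 1] - r[0, 1] ** 2
                  + r[0, 0] * r[2, 2] - r[0, 2] ** 2
                  + r[1, 1] * r[2, 2] - r[1, 2] ** 2)
        det = np.linalg.det(r)
        eigvals = np.sort(np.roots([-1.0, tr, -minors, det]).real)[::-1]
        # explained_variance holds the first two components' fractions
        assert np.allclose(ms.explained_variance[0] * eigvals.sum(),
                           eigvals[:2], atol=1e-8)
        # eigenvector of the top eigenvalue via null space of (R - lambda I)
        m = r - eigvals[0] * np.eye(3)
        _, _, vt = np.linalg.svd(m)
        v = vt[-1]
        if v[0] < 0:
            v = -v  # package sign convention: first variable loads positive
        expected_pc1 = z.to_numpy() @ v
        assert np.allclose(ms.scores[(0, "pc1")], expected_pc1, atol=1e-8)

    def test_scores_zero_mean(self, small_cohort):
        data = small_cohort.set_index("id")[["rice", "wheat", "fibre", "iron"]]
        ms = net.module_scores(
            data, self._modules({"rice": 0, "wheat": 0, "fibre": 1, "iron": 1}))
        assert np.allclose(ms.scores.mean(), 0.0, atol=1e-8)

    def test_zero_variance_variable_dropped(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame({"a": rng.normal(0, 1, 20),
                             "b": np.full(20, 2.0)})
        with pytest.warns(UserWarning, match="zero-variance"):
            ms = net.module_scores(data, self._modules({"a": 0, "b": 0}))
        assert list(ms.loadings[0].index) == ["a"]


class TestPipelineRecovery:
    def test_two_block_structure_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            z1, z2 = rng.standard_normal((n, 1)), rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, 6))
            x = np.hstack([
                np.sqrt(0.8) * z1 + np.sqrt(0.2) * noise[:, :3],
                np.sqrt(0.8) * z2 + np.sqrt(0.2) * noise[:, 3:]])
            df = pd.DataFrame(x, columns=["a1", "a2", "a3", "b1", "b2", "b3"])
            sex = np.array(["female"] * 100 + ["male"] * 100)
            ms = net.detect_modules(net.prune_spanning_tree(
                net.sex_weighted_spearman(df, sex)))
            mods = sorted(map(sorted, ms.modules().values()))
            if mods == [["a1", "a2", "a3"], ["b1", "b2", "b3"]]:
                hits += 1
        assert hits >= 19
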