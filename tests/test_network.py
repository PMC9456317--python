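import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from qsig.io import ExpressionMatrix, GeneSetCollection
from qsig.network import (GeneNetwork, betweenness_centrality,
                          build_coexpression_network, class_partition,
                          clustering_coefficients, edge_count_comparison,
                          giant_component, pathway_distribution,
                          rewiring_report, write_sif)


# ---------------------------------------------------------------- oracles
def brute_force_betweenness(G):
    """All-pairs enumeration of shortest paths; fractional credit across
    ties; unordered pairs counted once; endpoints excluded."""
    nodes = sorted(G.nodes)
    bw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(G, s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                bw[v] += 1.0 / len(paths)
    return bw


def _all_shortest_paths(G, s, t):
    # BFS distances then DFS over the shortest-path DAG
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in G[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    if t not in dist:
        return []
    paths, stack = [], [[t]]
    while stack:
        path = stack.pop()
        head = path[-1]
        if head == s:
            paths.append(path[::-1])
            continue
        for w in G[head]:
            if dist.get(w, -1) == dist[head] - 1:
                stack.append(path + [w])
    return paths


def brute_force_clustering(G):
    cc = {}
    for v in sorted(G.nodes):
        nbrs = list(G[v])
        if len(nbrs) < 2:
            cc[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2)
                    if G.has_edge(a, b))
        cc[v] = links / (len(nbrs) * (len(nbrs) - 1) / 2)
    return cc


def union_find_components(G):
    parent = {v: v for v in G.nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in G.edges:
        parent[find(a)] = find(b)
    comps = {}
    for v in G.nodes:
        comps.setdefault(find(v), set()).add(v)
    return sorted((sorted(c) for c in comps.values()), key=lambda c: (-len(c), c[0]))


def _random_graphs(n_graphs=50, max_nodes=8, seed=99):
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.15, 0.8))
        G = nx.Graph()
        G.add_nodes_from(f"N{i}" for i in range(n))
        for a, b in itertools.combinations(sorted(G.nodes), 2):
            if rng.random() < p:
                G.add_edge(a, b)
        graphs.append(G)
    return graphs


def _net(G, threshold=0.7, label="all"):
    return GeneNetwork(G, threshold=threshold, subset_label=label)


def _logmat(vals, genes=None, samples=None):
    genes = genes or [f"G{i:03d}" for i in range(vals.shape[0])]
    samples = samples or [f"s{j}" for j in range(vals.shape[1])]
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples),
                            scale="log_generic")


# ---------------------------------------------------------------- builders
class TestBuildNetwork:
    def test_affine_copy_gives_edge(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = _logmat(np.vstack([x, 2 * x + 5]))
        net = build_coexpression_network(m, r_threshold=0.7)
        assert net.n_edges == 1
        assert net.edge_frame()["r"].iloc[0] == pytest.approx(1.0)

    def test_threshold_one_gives_no_edges(self, rng):
        m = _logmat(rng.normal(size=(8, 5)))
        assert build_coexpression_network(m, r_threshold=1.0).n_edges == 0

    def test_edges_match_double_loop_oracle(self, rng):
        vals = rng.normal(size=(15, 6))
        m = _logmat(vals)
        net = build_coexpression_network(m, r_threshold=0.5)
        expect = set()
        for i, j in itertools.combinations(range(15), 2):
            r = np.corrcoef(vals[i], vals[j])[0, 1]
            if abs(r) > 0.5:
                expect.add((m.gene_ids[i], m.gene_ids[j]))
        got = {(a, b) for a, b, _ in net.edge_frame().itertuples(index=False,
                                                                name=None)}
        assert got == expect

    def test_threshold_monotone_nesting(self, rng):
        vals = rng.normal(size=(12, 5))
        m = _logmat(vals)
        lo = build_coexpression_network(m, r_threshold=0.3)
        hi = build_coexpression_network(m, r_threshold=0.7)
        lo_edges = set(map(frozenset, lo.graph.edges))
        hi_edges = set(map(frozenset, hi.graph.edges))
        assert hi_edges <= lo_edges

    def test_zero_variance_genes_dropped_with_warning(self, rng):
        vals = rng.normal(size=(5, 4))
        vals[2] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            net = build_coexpression_network(_logmat(vals), r_threshold=0.9)
        assert "G002" not in net.graph

    def test_too_few_samples_is_error(self, rng):
        with pytest.raises(ValueError, match=">=3 samples"):
            build_coexpression_network(_logmat(np.zeros((4, 2))))


# ---------------------------------------------------------------- centrality
class TestCentrality:
    def test_path_graph_middle_node(self):
        net = _net(nx.path_graph(["A", "B", "C"]))
        bw = betweenness_centrality(net)["betweenness"]
        assert bw["B"] == pytest.approx(1.0)
        assert bw["A"] == bw["C"] == 0.0

    def test_star_center_pair_count(self):
        G = nx.star_graph(4)
        G = nx.relabel_nodes(G, {i: f"N{i}" for i in G.nodes})
        bw = betweenness_centrality(_net(G))["betweenness"]
        assert bw["N0"] == pytest.approx(6.0)  # C(4,2)
        assert all(bw[f"N{i}"] == 0 for i in range(1, 5))

    def test_triangle_clustering_all_one(self):
        net = _net(nx.complete_graph(["A", "B", "C"]))
        assert (clustering_coefficients(net)["clustering"] == 1.0).all()

    def test_star_clustering_all_zero(self):
        G = nx.relabel_nodes(nx.star_graph(4), {i: f"N{i}" for i in range(5)})
        assert (clustering_coefficients(_net(G))["clustering"] == 0.0).all()

    @pytest.mark.parametrize("graph_idx", range(0, 50, 7))
    def test_betweenness_and_clustering_match_brute_force(self, graph_idx):
        G = _random_graphs()[graph_idx]
        net = _net(G)
        bw = betweenness_centrality(net)["betweenness"]
        oracle_bw = brute_force_betweenness(G)
        for v in G.nodes:
            assert bw[v] == pytest.approx(oracle_bw[v], abs=1e-9)
        cc = clustering_coefficients(net)["clustering"]
        oracle_cc = brute_force_clustering(G)
        for v in G.nodes:
            assert cc[v] == pytest.approx(oracle_cc[v], abs=1e-12)

    def test_betweenness_conservation_against_path_oracle(self):
        """Total betweenness equals the summed fractional intermediate-node
        incidences over all shortest paths."""
        for G in _random_graphs(n_graphs=10, seed=7):
            total = betweenness_centrality(_net(G))["betweenness"].sum()
            oracle = sum(brute_force_betweenness(G).values())
            assert total == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------- components
class TestComponents:
    def test_two_triangles_plus_isolate(self):
        G = nx.Graph()
        G.add_edges_from([("A", "B"), ("B", "C"), ("A", "C"),
                          ("X", "Y"), ("Y", "Z"), ("X", "Z")])
        G.add_node("Q")
        giant, sizes = giant_component(_net(G))
        assert len(giant) == 3 and sizes == [3, 3, 1]
        assert giant == ["A", "B", "C"]  # tie -> smallest member

    def test_complete_graph_is_giant(self):
        G = nx.complete_graph([f"N{i}" for i in range(5)])
        giant, sizes = giant_component(_net(G))
        assert giant == sorted(G.nodes) and sizes == [5]

    def test_partition_matches_union_find_oracle(self):
        for G in _random_graphs(n_graphs=15, seed=13):
            giant, sizes = giant_component(_net(G))
            oracle = union_find_components(G)
            assert giant == oracle[0]
            assert sizes == [len(c) for c in oracle]

    def test_empty_network(self):
        giant, sizes = giant_component(_net(nx.Graph()))
        assert giant == [] and sizes == []


class TestClassPartition:
    def test_identical_networks_no_exclusive_members(self):
        G = nx.path_graph(["A", "B", "C"])
        cls = class_partition(_net(G), _net(G.copy()), ["A", "B", "C", "D"])
        assert cls.plus_only == [] and cls.minus_only == []
        assert cls.shared == ["A", "B", "C"]

    def test_disjoint_giants_share_nothing(self):
        Gp = nx.path_graph(["A", "B", "C"])
        Gm = nx.path_graph(["X", "Y", "Z"])
        for n in ("X", "Y", "Z"):
            Gp.add_node(n)
        for n in ("A", "B", "C"):
            Gm.add_node(n)
        cls = class_partition(_net(Gp), _net(Gm), list("ABCXYZ"))
        assert cls.shared == []
        assert cls.plus_only == ["A", "B", "C"]
        assert cls.minus_only == ["X", "Y", "Z"]

    def test_universe_violation_is_error(self):
        G = nx.path_graph(["A", "B"])
        with pytest.raises(ValueError, match="universe"):
            class_partition(_net(G), _net(G.copy()), ["A"])


# ---------------------------------------------------------------- rewiring
class TestRewiring:
    def _cent(self, values):
        return pd.DataFrame({"betweenness": values},
                            index=[f"G{i}" for i in range(len(values))])

    def test_identical_centralities_zero_discordance(self):
        c = self._cent([5.0, 3.0, 1.0, 0.0])
        rep = rewiring_report(c, c.copy())
        assert (rep["discordance"] == 0).all()
        assert not rep["flagged"].any()

    def test_swapped_pair_flagged_on_top(self):
        cp = self._cent([10.0, 8.0, 6.0, 4.0, 2.0, 0.0])
        cm = cp.copy()
        cm.loc["G0", "betweenness"], cm.loc["G5", "betweenness"] = 0.0, 10.0
        rep = rewiring_report(cp, cm)
        top = rep.sort_values("discordance", ascending=False).index[:2]
        assert set(top) == {"G0", "G5"}
        assert rep.loc["G0", "flagged"] and rep.loc["G5", "flagged"]

    def test_mean_betweenness_reported(self):
        rep = rewiring_report(self._cent([4.0, 0.0]), self._cent([2.0, 2.0]))
        assert rep.attrs["mean_betweenness"] == {"plus": 2.0, "minus": 2.0}

    def test_synthetic_rewired_module_flagged_above_chance(self):
        """Genes whose latent-factor loading is active in only one state
        (the planted rewiring) are over-represented among the flagged
        high-discordance genes, on a 20-seed average."""
        from qsig.simulate import SimConfig, TissueSpec, generate_experiment
        from qsig.io import log_cpm
        excess = []
        for seed in range(1, 21):
            counts, designs, truth, _ = generate_experiment(SimConfig(
                seed=seed, n_genes=300, signature_size=40, module_size=24,
                module_strength=1.0,
                tissues=[TissueSpec("t", 1, 10)], n_decoy_sets=2))
            logm = log_cpm(counts["t"])
            design = designs["t"].set_index("sample")
            plus = [s for s in logm.sample_ids
                    if design.loc[s, "phenotype"] == "PKH26_plus"]
            minus = [s for s in logm.sample_ids
                     if design.loc[s, "phenotype"] == "PKH26_minus"]
            wp, wm = truth.module_loadings["plus"], truth.module_loadings["minus"]
            rewired = {g for g in truth.module_members
                       if (wp[g] != 0) != (wm[g] != 0)}
            if not rewired:
                continue
            np_ = build_coexpression_network(logm, truth.module_members,
                                             plus, 0.85, "plus")
            nm_ = build_coexpression_network(logm, truth.module_members,
                                             minus, 0.85, "minus")
            rep = rewiring_report(betweenness_centrality(np_),
                                  betweenness_centrality(nm_))
            flagged = set(rep.index[rep["flagged"]])
            if flagged:
                excess.append(len(flagged & rewired) / len(flagged)
                              - len(rewired) / len(truth.module_members))
        assert len(excess) >= 15
        assert np.mean(excess) > 0


# ---------------------------------------------------------------- range restriction
from qsig.simulate import make_anti_pooling_example as anti_pooling_fixture  # noqa: E402


class TestEdgeCountComparison:
    def test_anti_pooling_fixture_state_networks_denser(self):
        m, design, module = anti_pooling_fixture()
        comp = edge_count_comparison(m, design, module, threshold=0.7)
        assert comp["edges"]["plus"] > comp["edges"]["all"]
        assert comp["edges"]["minus"] > comp["edges"]["all"]
        assert comp["intra_exceeds_pooled"]
        # verify against direct correlation computation on plus samples
        plus_vals = m.data[[c for c in m.sample_ids if c.startswith("p")]]
        R = np.corrcoef(plus_vals.loc[module])
        iu = np.triu_indices(len(module), 1)
        assert comp["edges"]["plus"] == int((np.abs(R[iu]) > 0.7).sum())

    def test_pure_noise_counts_small_and_comparable(self, rng):
        vals = rng.normal(size=(20, 12))
        m = _logmat(vals, samples=[f"p{i}" for i in range(6)] +
                    [f"m{i}" for i in range(6)])
        design = pd.DataFrame({
            "sample": m.sample_ids, "tissue": "t", "line": "l1",
            "phenotype": ["PKH26_plus"] * 6 + ["PKH26_minus"] * 6,
            "replicate": list(range(6)) * 2})
        comp = edge_count_comparison(m, design, m.gene_ids, threshold=0.95)
        assert max(comp["edges"].values()) <= 10

    def test_shared_global_factor_pooled_at_least_as_dense(self, rng):
        z = rng.normal(size=12)
        rows = [5 + z + rng.normal(0, 0.05, 12) for _ in range(10)]
        m = _logmat(np.array(rows), samples=[f"p{i}" for i in range(6)] +
                    [f"m{i}" for i in range(6)])
        design = pd.DataFrame({
            "sample": m.sample_ids, "tissue": "t", "line": "l1",
            "phenotype": ["PKH26_plus"] * 6 + ["PKH26_minus"] * 6,
            "replicate": list(range(6)) * 2})
        comp = edge_count_comparison(m, design, m.gene_ids, threshold=0.7)
        assert comp["edges"]["all"] >= max(comp["edges"]["plus"],
                                           comp["edges"]["minus"])


# ---------------------------------------------------------------- pathways
class TestPathwayDistribution:
    def test_identical_columns_perfect_correlation(self):
        coll = GeneSetCollection({"P1": frozenset({"A", "B"}),
                                  "P2": frozenset({"B", "C"}),
                                  "P3": frozenset({"C", "D"})})
        classes = {"x": ["A", "B", "C"], "y": ["A", "B", "C"]}
        counts, corr = pathway_distribution(classes, coll)
        assert corr.loc["x", "y"] == pytest.approx(1.0)

    def test_symmetric_with_unit_diagonal(self, rng):
        genes = [f"G{i:02d}" for i in range(30)]
        coll = GeneSetCollection(
            {f"P{i}": frozenset(rng.choice(genes, 8, replace=False))
             for i in range(6)})
        classes = {k: list(rng.choice(genes, 12, replace=False))
                   for k in ("plus", "minus", "all")}
        counts, corr = pathway_distribution(classes, coll)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)

    def test_counts_match_direct_formula(self, rng):
        genes = [f"G{i:02d}" for i in range(20)]
        coll = GeneSetCollection(
            {f"P{i}": frozenset(rng.choice(genes, 6, replace=False))
             for i in range(4)})
        classes = {"a": genes[:10], "b": genes[5:15]}
        counts, corr = pathway_distribution(classes, coll)
        a = counts["a"].to_numpy(dtype=float)
        b = counts["b"].to_numpy(dtype=float)
        expect = np.corrcoef(a, b)[0, 1]
        assert corr.loc["a", "b"] == pytest.approx(expect, abs=1e-12)

    def test_empty_collection_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            pathway_distribution({"a": []}, GeneSetCollection({}))


def test_sif_export_format(tmp_path):
    G = nx.Graph()
    G.add_edge("GB", "GA", r=0.9)
    write_sif(_net(G), tmp_path / "n.sif")
    assert (tmp_path / "n.sif").read_text() == "GA\tpp\tGB\n"
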