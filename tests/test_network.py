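"""PCC edges, bait selection, BFS levels, hubs, and network export."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from togcn.exceptions import ConstantProfileError, ParameterError
from togcn.expression import TREATMENTS, ExpressionMatrix, treatment_means
from togcn.network import (
    BaitCriterion,
    assign_levels_bfs,
    build_edges,
    export_network,
    hub_statistics,
    pcc,
    read_network,
    select_bait_genes,
)


def direct_formula_pcc(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def matrix_from(rows: dict, reps: int = 3) -> ExpressionMatrix:
    samples = [f"{t}_r{j}" for t in TREATMENTS for j in range(1, reps + 1)]
    return ExpressionMatrix(
        values=pd.DataFrame(rows, index=samples).T,
        sample_treatments={s: s.split("_")[0] for s in samples},
    )


class TestPcc:
    def test_self_correlation(self):
        x = np.arange(18.0)
        assert pcc(x, x) == 1.0
        assert pcc(x, -x) == -1.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x, y = rng.normal(size=18), rng.normal(size=18)
            assert pcc(x, y) == pytest.approx(direct_formula_pcc(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantProfileError):
            pcc([1.0] * 18, list(range(18)))

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            pcc([1, 2], [3, 4])


class TestBuildEdges:
    def test_inclusive_threshold_at_exact_cutoff(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=18)
        z = rng.normal(size=18)
        xs = (x - x.mean()) / x.std()
        zs = z - z.mean()
        zs -= zs @ xs / (xs @ xs) * xs  # orthogonalise
        zs /= zs.std()
        r = 0.93
        y = r * xs + math.sqrt(1 - r * r) * zs
        m = matrix_from({"tf": 10 + xs, "g": 10 + y})
        # reproduce the builder's standardized dot product bit-for-bit so the
        # cutoff can be set to the exact observed correlation
        arr = m.values.to_numpy(dtype=float)
        arr = arr - arr.mean(axis=1, keepdims=True)
        arr = arr / np.sqrt((arr ** 2).sum(axis=1, keepdims=True))
        observed = float(np.clip(arr[:1] @ arr[1:].T, -1.0, 1.0)[0, 0])
        assert observed == pytest.approx(r, abs=0.05)
        graph = build_edges(m, {"tf"}, pcc_min=observed)  # equality must pass
        assert graph.has_edge("tf", "g")
        graph2 = build_edges(m, {"tf"}, pcc_min=np.nextafter(observed, 1.0))
        assert not graph2.has_edge("tf", "g")

    def test_noiseless_modules_give_exactly_planted_edges(self):
        from togcn import synthetic

        matrix, truth = synthetic.generate_expression(
            n_genes=80, n_tf=10, noise_sd=0.0, seed=11
        )
        graph = build_edges(matrix, truth.tf_ids, pcc_min=0.9)
        found = {frozenset(e) for e in graph.edges()}
        assert found == truth.planted_edges()

    def test_default_fixture_recall_and_false_edges(self, network_fixture):
        graph = network_fixture["graph"]
        truth = network_fixture["truth"]
        planted = truth.planted_edges()
        found = {frozenset(e) for e in graph.edges()}
        recall = len(found & planted) / len(planted)
        false_rate = len(found - planted) / max(1, len(found))
        assert recall >= 0.95
        assert false_rate <= 0.01

    def test_tf_scope_excludes_tf_tf_edges(self, network_fixture):
        graph = network_fixture["graph"]
        tfs = network_fixture["truth"].tf_ids
        assert not any(u in tfs and v in tfs for u, v in graph.edges())

    def test_tf_vs_all_adds_tf_tf_edges(self, filtered_fixture):
        graph = build_edges(
            filtered_fixture["filtered"], filtered_fixture["truth"].tf_ids,
            pair_scope="tf_vs_all",
        )
        tfs = filtered_fixture["truth"].tf_ids
        assert any(u in tfs and v in tfs for u, v in graph.edges())

    def test_threshold_monotone(self, filtered_fixture):
        lo = build_edges(filtered_fixture["filtered"],
                         filtered_fixture["truth"].tf_ids, pcc_min=0.9)
        hi = build_edges(filtered_fixture["filtered"],
                         filtered_fixture["truth"].tf_ids, pcc_min=0.95)
        assert set(map(frozenset, hi.edges())) <= set(map(frozenset, lo.edges()))

    def test_no_self_or_duplicate_edges(self, network_fixture):
        graph = network_fixture["graph"]
        assert not any(u == v for u, v in graph.edges())

    def test_empty_tf_set_rejected(self, filtered_fixture):
        with pytest.raises(ParameterError):
            build_edges(filtered_fixture["filtered"], {"nope"})


class TestBaits:
    def make_means(self, profile):
        return pd.DataFrame([profile], index=["g"], columns=TREATMENTS)

    def test_strictly_decreasing_selected(self):
        assert select_bait_genes(self.make_means([10, 8, 6, 4, 2, 1])) == {"g"}

    def test_interior_peak_rejected(self):
        assert select_bait_genes(self.make_means([10, 12, 6, 4, 2, 1])) == set()

    def test_flat_rejected(self):
        assert select_bait_genes(self.make_means([5, 5, 5, 5, 5, 5])) == set()

    def test_small_wobble_within_band_accepted(self):
        assert select_bait_genes(self.make_means([10, 6, 6.5, 4, 2, 1])) == {"g"}

    def test_zero_tolerance_requires_strict_decrease(self):
        crit = BaitCriterion(rel_tol=0.0)
        assert select_bait_genes(self.make_means([10, 6, 6.5, 4, 2, 1]), crit) == set()
        assert select_bait_genes(self.make_means([10, 8, 6, 4, 2, 1]), crit) == {"g"}

    def test_recovers_planted_bait_set(self, filtered_fixture):
        baits = select_bait_genes(filtered_fixture["means"], BaitCriterion(0.1))
        assert baits == filtered_fixture["truth"].bait_ids


class TestLevels:
    def test_path_levels(self):
        g = nx.path_graph(["bait", "A", "B"])
        assign_levels_bfs(g, {"bait"})
        assert [g.nodes[n]["level"] for n in ("bait", "A", "B")] == [1, 2, 3]

    def test_isolated_node_unassigned(self):
        g = nx.Graph()
        g.add_edge("bait", "A")
        g.add_node("island")
        unassigned = assign_levels_bfs(g, {"bait"})
        assert unassigned == ["island"]
        assert "level" not in g.nodes["island"]

    def test_multi_source_takes_nearest_bait(self):
        g = nx.path_graph(["b1", "x", "y", "b2"])
        assign_levels_bfs(g, {"b1", "b2"})
        assert g.nodes["x"]["level"] == 2 and g.nodes["y"]["level"] == 2

    def test_empty_bait_set_rejected(self):
        with pytest.raises(ParameterError):
            assign_levels_bfs(nx.path_graph(3), set())

    def test_matches_floyd_warshall_on_random_graphs(self):
        from scipy.sparse.csgraph import floyd_warshall

        rng = np.random.default_rng(99)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            p = float(rng.uniform(0.02, 0.15))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            baits = set(int(b) for b in
                        rng.choice(n, size=int(rng.integers(1, 4)), replace=False))
            assign_levels_bfs(g, baits)
            adj = nx.to_numpy_array(g, nodelist=range(n), weight=None)
            dist = floyd_warshall(adj, unweighted=True)
            expected = dist[sorted(baits)].min(axis=0)
            for node in range(n):
                if np.isinf(expected[node]):
                    assert "level" not in g.nodes[node]
                else:
                    assert g.nodes[node]["level"] == int(expected[node]) + 1

    def test_invariant_to_edge_insertion_order(self):
        edges = [(0, 1), (1, 2), (2, 3), (0, 3), (3, 4)]
        g1, g2 = nx.Graph(edges), nx.Graph(reversed(edges))
        assign_levels_bfs(g1, {0})
        assign_levels_bfs(g2, {0})
        assert {n: g1.nodes[n]["level"] for n in g1} == \
               {n: g2.nodes[n]["level"] for n in g2}


class TestHubs:
    def test_star_degrees(self):
        g = nx.star_graph(5)  # center 0, leaves 1..5
        table = hub_statistics(g)
        assert table.iloc[0].gene_id == 0 and table.iloc[0].degree == 5
        assert (table.degree.iloc[1:] == 1).all()

    def test_tie_break_by_gene_id(self):
        g = nx.Graph([("b", "x"), ("a", "y")])
        table = hub_statistics(g)
        assert list(table.gene_id) == ["a", "b", "x", "y"]

    def test_planted_hub_tops_ranking(self, network_fixture):
        table = hub_statistics(network_fixture["graph"],
                               focus_ids=network_fixture["truth"].tf_ids)
        # every module TF correlates with all module partners: top degree = module size
        assert table.iloc[0].degree == 20


class TestExport:
    @pytest.fixture()
    def small_graph(self):
        g = nx.Graph()
        g.add_node("tf1", is_tf=True, level=1)
        g.add_node("g1", is_tf=False, level=2)
        g.add_node("lonely", is_tf=False)
        g.add_edge("tf1", "g1", weight=0.951234567)
        return g

    def test_edgelist_round_trip(self, small_graph, tmp_path):
        path = tmp_path / "net.tsv"
        export_network(small_graph, path, fmt="edgelist")
        back = read_network(path, fmt="edgelist")
        assert set(back.nodes) == set(small_graph.nodes)
        assert set(map(frozenset, back.edges())) == set(map(frozenset, small_graph.edges()))
        assert back["tf1"]["g1"]["weight"] == small_graph["tf1"]["g1"]["weight"]
        assert back.nodes["tf1"]["level"] == 1
        assert "level" not in back.nodes["lonely"]

    def test_graphml_round_trip(self, small_graph, tmp_path):
        path = tmp_path / "net.graphml"
        export_network(small_graph, path, fmt="graphml")
        back = read_network(path, fmt="graphml")
        assert set(back.nodes) == set(small_graph.nodes)
        assert back["tf1"]["g1"]["weight"] == pytest.approx(0.951234567)

    def test_sif_line_count_equals_edges(self, small_graph, tmp_path):
        path = tmp_path / "net.sif"
        export_network(small_graph, path, fmt="sif")
        lines = [l for l in path.read_text().splitlines() if l]
        assert len(lines) == small_graph.number_of_edges()

    def test_empty_network_valid_file(self, tmp_path):
        path = tmp_path / "empty.sif"
        export_network(nx.Graph(), path, fmt="sif")
        assert path.exists() and path.read_text() == ""

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ParameterError):
            export_network(nx.Graph(), tmp_path / "x", fmt="dot")
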