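"""RMT threshold selection, network topology, modules, and node roles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import rand_index, two_block_config
from pmenet.pmen import (
    Pmen,
    SimilarityError,
    SimilarityMatrix,
    build_network,
    classify_role,
    correlation_matrix,
    detect_modules,
    modularity,
    nnsd_pvalue,
    node_roles,
    rmt_threshold,
    summarize_pmen,
    unfold_and_nnsd,
)
from pmenet.synthetic import generate_latent, sample_counts
from pmenet.tables import FeatureTable


def _sim_from(matrix, ids=None):
    ids = ids or [f"f{i}" for i in range(len(matrix))]
    return SimilarityMatrix(pd.DataFrame(matrix, index=ids, columns=ids))


class TestCorrelationMatrix:
    def _table(self, arr):
        return FeatureTable(
            pd.DataFrame(arr, index=[f"f{i}" for i in range(len(arr))],
                         columns=[f"s{i}" for i in range(len(arr[0]))])
        )

    def test_duplicated_feature_correlates_perfectly(self):
        base = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        sim = correlation_matrix(self._table([base, base, [1, 2, 3, 4, 5, 6]]))
        assert sim.values.loc["f0", "f1"] == pytest.approx(1.0)

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(3)
        arr = rng.uniform(1, 10, size=(3, 8))
        sim = correlation_matrix(self._table(arr), transform="none")
        rel = arr / arr.sum(axis=0)
        for i, j in itertools.combinations(range(3), 2):
            expected = stats.pearsonr(rel[i], rel[j]).statistic
            assert sim.values.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_antisymmetric_pair(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        arr = np.vstack([x, x[::-1], np.ones(5) * 2])
        sim = correlation_matrix(self._table(arr), transform="none")
        assert sim.values.loc["f0", "f1"] == pytest.approx(-1.0, abs=1e-9)

    def test_zero_variance_feature_excluded(self):
        arr = [[1, 2, 3, 4], [5, 5, 5, 5], [4, 3, 2, 1]]
        sim = correlation_matrix(self._table(arr), transform="none")
        assert "f1" not in sim.feature_ids

    def test_requires_four_samples(self):
        with pytest.raises(SimilarityError):
            correlation_matrix(self._table([[1, 2, 3], [3, 2, 1]]))


class TestUnfolding:
    def test_arithmetic_spectrum_unfolds_to_unit_spacings(self):
        s = unfold_and_nnsd(np.linspace(0, 10, 200))
        assert s.mean() == pytest.approx(1.0, abs=1e-6)
        assert s.var() < 1e-3

    def test_goe_spectrum_prefers_wigner(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((400, 400))
        eig = np.linalg.eigvalsh((a + a.T) / np.sqrt(2))
        s = unfold_and_nnsd(eig)
        assert nnsd_pvalue(s, "goe") > 0.05
        assert nnsd_pvalue(s, "poisson") < 1e-10

    def test_iid_spectrum_prefers_poisson(self):
        rng = np.random.default_rng(1)
        s = unfold_and_nnsd(np.sort(rng.uniform(0, 1, 400)))
        assert nnsd_pvalue(s, "poisson") > 0.05
        assert nnsd_pvalue(s, "goe") < 1e-10

    def test_too_few_or_degenerate_eigenvalues_rejected(self):
        with pytest.raises(SimilarityError):
            unfold_and_nnsd(np.arange(10.0))
        with pytest.raises(SimilarityError):
            unfold_and_nnsd(np.ones(50))


class TestRmtThreshold:
    def test_identity_matrix_has_no_links(self):
        scan = rmt_threshold(_sim_from(np.eye(30)))
        assert scan.chosen_threshold is None
        assert (scan.scan["total_links"] == 0).all()

    def test_saturated_matrix_keeps_high_threshold_or_none(self):
        m = np.full((30, 30), 0.96)
        np.fill_diagonal(m, 1.0)
        scan = rmt_threshold(_sim_from(m))
        assert scan.chosen_threshold is None or scan.chosen_threshold >= 0.95

    def test_planted_two_block_recovery(self):
        cfg = two_block_config(seed=42)
        latent, truth = generate_latent(cfg)
        counts = sample_counts(latent, cfg.sequencing_depth, seed=42)
        sim = correlation_matrix(counts)
        scan = rmt_threshold(sim)
        assert scan.chosen_threshold is not None
        assert scan.chosen_threshold < 0.9  # below the planted correlation
        g = build_network(sim, scan.chosen_threshold)
        part = detect_modules(g)
        nodes = list(g.nodes)
        ri = rand_index([truth.module_of[n] for n in nodes], [part[n] for n in nodes])
        assert ri > 0.9


class TestBuildNetwork:
    def test_triangle_forced(self):
        m = np.full((3, 3), 0.9)
        np.fill_diagonal(m, 1.0)
        g = build_network(_sim_from(m), 0.8)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3
        assert build_network(_sim_from(m), 0.95).number_of_edges() == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(-1, 1, (15, 15))
        m = np.clip((a + a.T) / 2, -1, 1)
        np.fill_diagonal(m, 1.0)
        sim = _sim_from(m)
        edges = [build_network(sim, t).number_of_edges() for t in (0.2, 0.4, 0.6, 0.8)]
        assert edges == sorted(edges, reverse=True)

    def test_signs_recorded(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = -0.9
        m[1, 2] = m[2, 1] = 0.9
        g = build_network(_sim_from(m), 0.8)
        assert g.edges["f0", "f1"]["sign"] == "-"
        assert g.edges["f1", "f2"]["sign"] == "+"


def _all_partitions(nodes):
    """Every set partition of ``nodes`` (Bell-number enumeration)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for smaller in _all_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


class TestModules:
    def _two_triangles(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        for u, v in g.edges:
            g.edges[u, v]["absweight"] = 1.0
        return g

    def test_disconnected_triangles_are_modules(self):
        part = detect_modules(self._two_triangles())
        assert len(set(part.values())) == 2
        assert part[0] == part[1] == part[2]
        assert part[3] == part[4] == part[5]

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(6)
        for u, v in g.edges:
            g.edges[u, v]["absweight"] = 1.0
        assert len(set(detect_modules(g).values())) == 1

    def test_two_triangle_modularity_closed_form(self):
        g = self._two_triangles()
        part = detect_modules(g)
        assert modularity(g, part) == pytest.approx(0.5)
        assert modularity(g, {n: 0 for n in g}) == pytest.approx(0.0)

    def test_missing_node_in_partition_rejected(self):
        g = self._two_triangles()
        with pytest.raises(ValueError):
            modularity(g, {0: 0})

    @pytest.mark.parametrize(
        "graph",
        [
            nx.path_graph(8),
            nx.cycle_graph(8),
            nx.barbell_graph(4, 0),
            nx.gnp_random_graph(8, 0.4, seed=1),
            nx.gnp_random_graph(8, 0.6, seed=2),
        ],
    )
    def test_greedy_q_near_exhaustive_optimum(self, graph):
        g = graph.copy()
        for u, v in g.edges:
            g.edges[u, v]["absweight"] = 1.0
        part = detect_modules(g)
        greedy_q = modularity(g, part)
        best = max(
            nx.algorithms.community.modularity(g, [set(b) for b in blocks])
            for blocks in _all_partitions(sorted(g.nodes))
        )
        assert greedy_q >= best - 0.05


class TestNodeRoles:
    @pytest.mark.parametrize(
        "zi,pi,role",
        [
            (3.0, 0.5, "module_hub"),
            (1.0, 0.7, "connector"),
            (3.0, 0.7, "network_hub"),
            (1.0, 0.5, "peripheral"),
        ],
    )
    def test_quoted_cutoff_categories(self, zi, pi, role):
        assert classify_role(zi, pi) == role

    def test_all_links_inside_module_gives_zero_pi(self):
        g = nx.complete_graph(4)
        roles = node_roles(g, {n: 0 for n in g})
        assert (roles["pi"] == 0).all()

    def test_degree_two_split_across_modules_gives_half(self):
        g = nx.Graph([("x", "a"), ("x", "b")])
        roles = node_roles(g, {"x": 0, "a": 0, "b": 1})
        assert roles.loc["x", "pi"] == pytest.approx(0.5)

    def test_brute_force_zi_pi_oracle_on_hand_built_graph(self):
        # 12 nodes in 3 modules with internal structure and cross links
        edges = [
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
            (4, 5), (4, 6), (4, 7), (5, 6),
            (8, 9), (8, 10), (8, 11), (9, 10), (10, 11),
            (3, 4), (7, 8), (2, 9), (3, 8),
        ]
        g = nx.Graph(edges)
        partition = {n: n // 4 for n in g}
        roles = node_roles(g, partition)
        for node in g:
            own = partition[node]
            members = [v for v in g if partition[v] == own]
            k_own = {v: sum(1 for u in g.neighbors(v) if partition[u] == own) for v in members}
            vals = list(k_own.values())
            mean = sum(vals) / len(vals)
            sd = (sum((v - mean) ** 2 for v in vals) / len(vals)) ** 0.5
            zi = 0.0 if sd == 0 else (k_own[node] - mean) / sd
            k = g.degree(node)
            counts = {}
            for u in g.neighbors(node):
                counts[partition[u]] = counts.get(partition[u], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in counts.values())
            assert roles.loc[node, "zi"] == pytest.approx(zi, abs=1e-12)
            assert roles.loc[node, "pi"] == pytest.approx(pi, abs=1e-12)
            assert roles.loc[node, "role"] == classify_role(zi, pi)

    def test_every_node_gets_exactly_one_role(self, default_study):
        sim = correlation_matrix(default_study["counts"])
        g = build_network(sim, 0.6)
        part = detect_modules(g)
        roles = node_roles(g, part)
        assert set(roles.index) == set(g.nodes)
        assert roles["role"].isin(
            ["module_hub", "network_hub", "connector", "peripheral"]
        ).all()
        # participation bounded by the number of modules a node touches
        for node in g.nodes:
            touched = len({part[u] for u in g.neighbors(node)})
            assert roles.loc[node, "pi"] <= 1 - 1 / touched + 1e-12


class TestSummary:
    @pytest.mark.parametrize(
        "n,l,expected",
        [(191, 351, 3.68), (84, 446, 10.62), (159, 478, 6.01)],
    )
    def test_average_connectivity_identity(self, n, l, expected):
        g = nx.gnm_random_graph(n, l, seed=0)
        for u, v in g.edges:
            g.edges[u, v].update(weight=1.0, absweight=1.0, sign="+")
        pmen = Pmen(graph=g, threshold=0.8, partition={x: 0 for x in g})
        s = summarize_pmen(pmen)
        assert s["avgK"] == pytest.approx(expected, abs=0.005)
        assert s["network_size"] == n and s["total_links"] == l

    def test_sign_percentages(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9, sign="+")
        g.add_edge("b", "c", weight=0.9, sign="+")
        g.add_edge("c", "d", weight=0.9, sign="+")
        g.add_edge("d", "a", weight=-0.9, sign="-")
        s = summarize_pmen(Pmen(graph=g, threshold=0.8, partition={x: 0 for x in g}))
        assert s["pct_positive"] == pytest.approx(75.0)
        assert s["pct_negative"] == pytest.approx(25.0)
        assert s["pct_positive"] + s["pct_negative"] == pytest.approx(100.0)
        assert s["avgK"] == pytest.approx(2.0)
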