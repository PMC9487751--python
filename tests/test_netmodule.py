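import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import pregmeth as pm
from pregmeth.experiments import cliques_oracle, diamond_oracle, harmonic_oracle
from pregmeth.netmodule import (
    EdgeFileError,
    build_consensus,
    build_network,
    colocalization_test,
    enumerate_maximal_cliques,
    harmonic_average_distance,
    load_string_edges,
    mcode_vertex_weights,
    module_to_cpgs,
    run_clique_sum,
    run_correlation_clique,
    run_diamond,
    run_mcode,
)


class TestLoadStringEdges:
    def _write(self, tmp_path, rows):
        path = tmp_path / "edges.tsv"
        path.write_text("protein1\tprotein2\tcombined_score\n" + "\n".join(rows) + "\n")
        return path

    def test_threshold_is_inclusive_at_900(self, tmp_path):
        path = self._write(tmp_path, ["A\tB\t900", "B\tC\t899"])
        net = load_string_edges(path)
        assert net.graph.has_edge("A", "B") and not net.graph.has_edge("B", "C")

    def test_duplicate_pairs_keep_max_score(self, tmp_path):
        path = self._write(tmp_path, ["A\tB\t950", "B\tA\t910"])
        net = load_string_edges(path)
        assert net.graph["A"]["B"]["score"] == 950
        assert net.n_edges == 1

    def test_three_row_toy_count(self, tmp_path):
        path = self._write(tmp_path, ["A\tB\t950", "B\tC\t920", "C\tD\t300"])
        assert load_string_edges(path).n_edges == 2

    def test_wrong_columns_raise(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(EdgeFileError):
            load_string_edges(path)

    def test_all_below_threshold_raises(self, tmp_path):
        path = self._write(tmp_path, ["A\tB\t100"])
        with pytest.raises(EdgeFileError):
            load_string_edges(path)

    def test_id_mapping_applied(self, tmp_path):
        path = self._write(tmp_path, ["ENSP1\tENSP2\t950"])
        net = load_string_edges(path, id_mapping={"ENSP1": "CD28", "ENSP2": "FYN"})
        assert set(net.graph.nodes) == {"CD28", "FYN"}


class TestColocalization:
    def test_path_graph_hand_value(self):
        g = nx.path_graph(["A", "B", "C"])
        assert harmonic_average_distance(g, ["A", "B", "C"]) == pytest.approx(1.2)

    def test_clique_seeds_attain_minimum(self):
        g = nx.complete_graph(6)
        assert harmonic_average_distance(g, [0, 1, 2, 3]) == 1.0

    def test_unreachable_pairs_give_infinity(self):
        g = nx.Graph()
        g.add_nodes_from(["A", "B"])
        assert math.isinf(harmonic_average_distance(g, ["A", "B"]))

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            genes = list(rng.choice(12, size=4, replace=False))
            ours = harmonic_average_distance(g, genes)
            oracle = harmonic_oracle(list(g.edges), list(g.nodes), genes)
            assert ours == pytest.approx(oracle) or (math.isinf(ours) and math.isinf(oracle))

    def test_permutation_p_bounds_and_unmapped_error(self):
        g = nx.complete_graph(10)
        net = pm.PPINetwork(g, 0)
        res = colocalization_test(net, [0, 1, 2], n_perm=99, seed=0)
        assert 0 < res.p <= 1
        assert len(res.null) == 99
        with pytest.raises(ValueError, match="unmapped"):
            colocalization_test(net, ["x", "y"], n_perm=99)

    def test_planted_clique_significant(self, planted_network):
        net, net_truth, _ = planted_network
        res = colocalization_test(net, net_truth.module_genes, n_perm=300, seed=0)
        assert res.d_obs == 1.0
        assert res.p <= 0.01
        assert res.d_obs < res.null_mean


class TestMcode:
    def test_vertex_weight_in_clique(self):
        # open neighbourhood of a k-clique vertex is a (k-1)-clique:
        # max core k-2, density 1
        for k in (4, 5, 6):
            w = mcode_vertex_weights(nx.complete_graph(k))
            assert w[0] == pytest.approx(k - 2)

    def test_top_complex_is_the_clique(self):
        g = nx.complete_graph(4)
        g.add_edge(3, 4)
        res = run_mcode(pm.PPINetwork(g, 0), seeds=[0])
        assert res.genes == {0, 1, 2, 3}

    def test_no_dense_region_gives_empty_module(self):
        g = nx.path_graph(6)
        res = run_mcode(pm.PPINetwork(g, 0), seeds=[0])
        assert res.genes == set()

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            run_mcode(pm.PPINetwork(nx.Graph(), 0), seeds=[])

    def test_complex_without_seed_excluded(self):
        g = nx.complete_graph(4)
        g.add_edges_from([(10, 11), (11, 12), (10, 12)])
        res = run_mcode(pm.PPINetwork(g, 0), seeds=[10])
        assert res.genes == {10, 11, 12}


class TestDiamond:
    def _toy(self):
        g = nx.Graph([("s1", "a"), ("s2", "a"), ("s1", "b")])
        return pm.PPINetwork(g, 0)

    def test_first_addition_is_the_doubly_connected_node(self):
        res = run_diamond(self._toy(), ["s1", "s2"], n_added=1)
        assert res.genes == {"s1", "s2", "a"}
        assert res.scores["a"] == 1.0

    def test_zero_additions_disallowed(self):
        with pytest.raises(ValueError):
            run_diamond(self._toy(), ["s1"], n_added=0)

    def test_no_seeds_in_network_raises(self):
        with pytest.raises(ValueError):
            run_diamond(self._toy(), ["zz"], n_added=1)

    def test_matches_exhaustive_recomputation(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 20))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
            g.add_edges_from(zip(range(n - 1), range(1, n)))
            seeds = [int(s) for s in rng.choice(n, size=3, replace=False)]
            res = run_diamond(pm.PPINetwork(g, 0), seeds, n_added=5)
            ours = sorted(res.scores, key=res.scores.get)
            assert ours == diamond_oracle(g, seeds, 5)


class TestCliqueSum:
    def test_all_seed_clique_in_sparse_background(self):
        g = nx.erdos_renyi_graph(100, 0.01, seed=1)
        g.add_edges_from((i, j) for i in range(4) for j in range(i + 1, 4))
        res = run_clique_sum(pm.PPINetwork(g, 0), [0, 1, 2, 3])
        assert res.genes == {0, 1, 2, 3}

    def test_no_seeded_clique_gives_empty_module(self):
        g = nx.complete_graph(5)
        g.add_node(99)
        res = run_clique_sum(pm.PPINetwork(g, 0), [99])
        assert res.genes == set()

    def test_enumeration_matches_subset_checking_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 14))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
            assert set(enumerate_maximal_cliques(g)) == cliques_oracle(g)

    def test_budget_exceeded_raises(self):
        g = nx.complete_graph(8)
        with pytest.raises(RuntimeError):
            run_clique_sum(pm.PPINetwork(g, 0), [0], max_cliques=0)


class TestCorrelationClique:
    def test_deterministic_limit_returns_the_clique(self):
        edges = [(f"s{i}", f"s{j}", 1000) for i in range(4) for j in range(i + 1, 4)]
        edges += [("s0", "x0", 1000)]
        edges += [(f"x{i}", f"x{i + 1}", 1000) for i in range(20)]
        net = build_network(edges, min_score=0)
        seeds = [f"s{i}" for i in range(4)]
        res = run_correlation_clique(net, seeds, {s: 1.0 for s in seeds}, n_iter=5, rng_seed=0)
        assert res.genes == set(seeds)

    def test_zero_retention_probability_empty_module(self):
        edges = [("a", "b", 0), ("b", "c", 0)]
        net = build_network(edges, min_score=0)
        res = run_correlation_clique(net, ["a", "b", "c"], n_iter=5, rng_seed=0)
        assert res.genes == set()

    def test_too_few_iterations_raise(self):
        net = build_network([("a", "b", 950), ("b", "c", 950)], min_score=0)
        with pytest.raises(ValueError):
            run_correlation_clique(net, ["a"], n_iter=1)

    def test_planted_high_score_clique_recovered_in_replicates(self, rng):
        # 5-clique of seeds at score 990 over a sparse 910-score background
        base = nx.gnp_random_graph(60, 0.05, seed=1)
        edges = [(f"n{u}", f"n{v}", 910) for u, v in base.edges]
        seeds = [f"s{i}" for i in range(5)]
        edges += [(a, b, 990) for i, a in enumerate(seeds) for b in seeds[i + 1 :]]
        edges += [("s0", "n0", 910)]
        net = build_network(edges, min_score=900)
        hits = 0
        for rep in range(20):
            res = run_correlation_clique(
                net, seeds, {s: 1.0 for s in seeds}, n_iter=50, freq_cutoff=0.5, rng_seed=7 + rep
            )
            hits += set(seeds) <= res.genes
        assert hits >= 19


class TestConsensus:
    def _results(self, membership):
        names = ["mcode", "diamond", "clique_sum", "correlation_clique"]
        return [
            pm.ModuleResult(method=name, genes={g for g, m in membership.items() if m[i]})
            for i, name in enumerate(names)
        ]

    def test_three_of_four_included_two_excluded(self):
        results = self._results({"a": (1, 1, 1, 0), "b": (1, 1, 0, 0)})
        cons = build_consensus(results)
        assert cons.genes == {"a"}

    def test_all_sixteen_membership_patterns(self):
        membership = {f"g{i}": tuple(int(b) for b in f"{i:04b}") for i in range(16)}
        cons = build_consensus(self._results(membership))
        expected = {f"g{i}" for i in range(16) if bin(i).count("1") >= 3}
        assert cons.genes == expected

    def test_duplicate_method_names_raise(self):
        results = self._results({"a": (1, 1, 1, 1)})
        results[1].method = "mcode"
        with pytest.raises(ValueError, match="duplicate"):
            build_consensus(results)

    def test_wrong_result_count_raises(self):
        with pytest.raises(ValueError):
            build_consensus(self._results({"a": (1, 1, 1, 1)})[:3])

    def test_consensus_is_subset_of_union(self, planted_network):
        net, net_truth, truth = planted_network
        seeds = [g for g in truth.effect_genes if g in net.nodes]
        results = [
            run_mcode(net, seeds),
            run_diamond(net, seeds, n_added=10),
            run_clique_sum(net, seeds),
            run_correlation_clique(net, seeds, {s: 1.0 for s in seeds}, n_iter=10, rng_seed=0),
        ]
        cons = build_consensus(results)
        union = set().union(*(r.genes for r in results))
        assert cons.genes <= union
        for r in results:
            assert r.genes <= net.nodes


class TestModuleToCpgs:
    def test_direct_lookup(self, small_cohort):
        (ds, truth), _ = small_cohort
        gene = truth.probe_gene_map.iloc[0]
        probes = truth.probe_gene_map[truth.probe_gene_map == gene].index
        dmp_table = pm.call_dmps(
            pm.fit_probe_models(
                pm.beta_to_m(ds.betas), pm.build_design(ds.samples)
            ).xs("T2_vs_NP", level="contrast"),
            pm.compute_delta_beta(ds.betas, ds.samples["group"], ("NP", "T2")),
        )
        out = module_to_cpgs([gene], ds.annotation, dmp_table)
        assert sorted(out.index) == sorted(probes)

    def test_gene_without_probes_skipped(self, small_cohort, caplog):
        (ds, _), _ = small_cohort
        dmp_table = pm.call_dmps(
            pd.DataFrame({"p": [0.5]}, index=[ds.betas.index[0]]),
            pd.Series([0.0], index=[ds.betas.index[0]]),
        )
        out = module_to_cpgs(["NOT_A_GENE"], ds.annotation, dmp_table)
        assert len(out) == 0
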