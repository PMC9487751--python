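import numpy as np
import pandas as pd
import pytest

import pregmeth as pm
from pregmeth.synth import preferential_attachment_edges, simulate_profiles


class TestSimulateProfiles:
    def test_single_cell_type_single_profile(self):
        mu, differing = simulate_profiles(100, 1, seed=0)
        assert mu.shape == (100, 1)
        assert differing == []

    def test_differing_probe_count_matches_bookkeeping(self):
        mu, differing = simulate_profiles(1000, 2, seed=1, differing_fraction=0.3)
        observed = np.where(np.abs(mu[:, 0] - mu[:, 1]) >= 0.2)[0]
        assert len(differing) == 300
        assert sorted(observed.tolist()) == differing

    @pytest.mark.parametrize("seed", [0, 5, 99])
    def test_entries_clipped(self, seed):
        mu, _ = simulate_profiles(500, 3, seed=seed)
        assert mu.min() >= 0.01 and mu.max() <= 0.99

    def test_invalid_dimensions_raise(self):
        with pytest.raises(ValueError):
            simulate_profiles(5, 2, seed=0)
        with pytest.raises(ValueError):
            simulate_profiles(100, 0, seed=0)


class TestSimulateCohort:
    def test_noiseless_limit_equals_mixture_mean(self):
        cfg = pm.SimulationConfig(
            n_probes=200, n_genes=20, seed=2, noise_precision=np.inf, effects=()
        )
        ds, truth = pm.simulate_cohort(cfg)
        expected = truth.mu.to_numpy() @ truth.omega.to_numpy().T
        assert np.allclose(ds.betas.to_numpy(), expected, atol=1e-12)

    def test_planted_delta_beta_recovered_in_expectation(self):
        """Monte-Carlo group mean difference on a planted +0.10 probe."""
        diffs = []
        for rep in range(50):
            cfg = pm.SimulationConfig(
                n_probes=300,
                n_genes=30,
                seed=1000 + rep,
                effects=(
                    pm.EffectSpec(group="T2", n_probes=10, delta_beta=(0.10, 0.10), frac_hyper=1.0),
                ),
            )
            ds, truth = pm.simulate_cohort(cfg)
            eff = truth.effect_table("T2")
            probe = eff.index[0]
            groups = ds.samples["group"]
            d = (
                ds.betas.loc[probe, groups[groups == "T2"].index].mean()
                - ds.betas.loc[probe, groups[groups == "NP"].index].mean()
            )
            # compare against the recorded signed delta (magnitude 0.10; the
            # generator flips the sign on probes without upward headroom)
            assert abs(eff.loc[probe]) == pytest.approx(0.10)
            diffs.append(d - eff.loc[probe])
        assert np.mean(diffs) == pytest.approx(0.0, abs=0.03)

    def test_group_sizes_follow_config(self, small_cohort):
        (ds, _), cfg = small_cohort
        counts = ds.samples["group"].value_counts().to_dict()
        assert counts == {"NP": 12, "T1": 11, "T2": 12}

    def test_betas_in_open_unit_interval(self, small_cohort):
        (ds, _), _ = small_cohort
        b = ds.betas.to_numpy()
        assert b.min() > 0 and b.max() < 1

    def test_omega_rows_on_simplex(self, small_cohort):
        (_, truth), _ = small_cohort
        om = truth.omega.to_numpy()
        assert np.allclose(om.sum(axis=1), 1.0, atol=1e-8)
        assert om.min() >= 0

    def test_planted_delta_converges_with_large_groups(self):
        cfg = pm.SimulationConfig(
            n_probes=300,
            n_genes=30,
            seed=5,
            groups=(("NP", 200, (0.6, 0.4)), ("T2", 200, (0.45, 0.55))),
            effects=(pm.EffectSpec(group="T2", n_probes=20, delta_beta=(0.10, 0.10), frac_hyper=1.0),),
        )
        ds, truth = pm.simulate_cohort(cfg)
        eff = truth.effect_table("T2")
        db = pm.compute_delta_beta(ds.betas, ds.samples["group"], ("NP", "T2"))
        assert np.allclose(db.loc[eff.index], eff.to_numpy(), atol=0.01)

    def test_mismatched_proportions_raise(self):
        with pytest.raises(ValueError, match="k_true"):
            pm.SimulationConfig(k_true=3, groups=(("NP", 5, (0.5, 0.5)),))


class TestSimulateNetwork:
    def test_preferential_attachment_edge_count(self, rng):
        edges = preferential_attachment_edges(200, 2, rng)
        assert len(edges) == 2 * (200 - 2) + 1
        # brute-force verification of the construction arithmetic
        m = 2
        assert len(edges) == m * (200 - m - 1) + m * (m + 1) // 2

    def test_planted_clique_is_complete(self, planted_network):
        net, net_truth, _ = planted_network
        sub = net.graph.subgraph(net_truth.module_genes)
        k = len(net_truth.module_genes)
        assert sub.number_of_edges() == k * (k - 1) // 2

    def test_all_scores_at_or_above_threshold(self, planted_network):
        net, _, _ = planted_network
        scores = [s for _, _, s in net.graph.edges(data="score")]
        assert min(scores) >= 900

    def test_module_genes_overlap_effect_genes(self, planted_network):
        _, net_truth, truth = planted_network
        assert set(net_truth.module_genes) <= set(truth.effect_genes)

    def test_too_small_module_raises(self):
        cfg = pm.SimulationConfig(network=pm.NetworkSpec(module_size=2))
        with pytest.raises(ValueError):
            pm.simulate_network(cfg)


class TestSimulateDiseaseCohort:
    def test_positive_sign_gives_exact_proportionality(self, small_cohort):
        (_, truth), cfg = small_cohort
        spec = pm.DiseaseSpec(effect_sign=1, n_shared_probes=20)
        _, dtruth = pm.simulate_disease_cohort(cfg, truth, disease=spec)
        preg = truth.effect_table("T2")
        dis = dtruth.effect_table("case")
        r = np.corrcoef(preg.loc[dis.index], dis)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_negative_sign_flips_every_generating_difference(self, small_cohort):
        (_, truth), cfg = small_cohort
        spec = pm.DiseaseSpec(effect_sign=-1, n_shared_probes=20)
        _, dtruth = pm.simulate_disease_cohort(cfg, truth, disease=spec)
        preg = truth.effect_table("T2")
        dis = dtruth.effect_table("case")
        assert np.all(np.sign(dis.to_numpy()) == -np.sign(preg.loc[dis.index].to_numpy()))

    def test_overlap_floor_rule(self, small_cohort):
        (_, truth), cfg = small_cohort
        spec = pm.DiseaseSpec(n_controls=10, overlap_fraction=0.3)
        _, dtruth = pm.simulate_disease_cohort(cfg, truth, disease=spec)
        assert len(dtruth.overlap_controls) == 3

    def test_overlap_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            pm.DiseaseSpec(overlap_fraction=1.0)


class TestWriters:
    def test_cohort_round_trip(self, small_cohort, tmp_path):
        (ds, truth), _ = small_cohort
        pm.synth.write_cohort(ds, truth, tmp_path)
        betas = pd.read_csv(tmp_path / "betas.tsv", sep="\t", index_col=0)
        assert betas.shape == ds.betas.shape
        assert np.allclose(betas.to_numpy(), ds.betas.to_numpy())

    def test_gmt_round_trip(self, tmp_path):
        sets = {"a": ["G1", "G2"], "b": ["G3"]}
        pm.synth.write_gmt(sets, tmp_path / "x.gmt")
        back = pm.synth.read_gmt(tmp_path / "x.gmt")
        assert back == {"a": ["G1", "G2"], "b": ["G3"]}
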