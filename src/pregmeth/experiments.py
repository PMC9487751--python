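"""Study-scale verification experiments over the synthetic generator.

Each function runs one self-contained study — oracle equivalence of the
network primitives, statistical calibration under the null, parameter and
signal recovery, and end-to-end directionality — and returns a small dict of
summary numbers.  The analysis drivers, the test suite and the acceptance
script all call these, so the numbers they report are computed one way.

Problem sizes are chosen for desk-scale verification (thousands of probes,
hundreds of network nodes); the statistical structure, sample sizes and
planted effect magnitudes follow the generator defaults.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .deconv import reffree_decompose, select_k, validate_against_reference
from .diffmeth import (
    adjust_fdr,
    build_design,
    call_dmps,
    compute_delta_beta,
    fit_probe_models,
    map_dmps_to_genes,
)
from .disease import (
    cpg_enrichment,
    direction_correlation,
    fisher_margin_scan,
    fisher_table,
    vista_subgroups,
)
from .netmodule import (
    PPINetwork,
    build_consensus,
    colocalization_test,
    diamond_pvalue,
    enumerate_maximal_cliques,
    harmonic_average_distance,
    module_to_cpgs,
    run_clique_sum,
    run_correlation_clique,
    run_diamond,
    run_mcode,
)
from .preprocess import beta_to_m, bmiq_normalize, filter_probes
from .synth import (
    DiseaseSpec,
    EffectSpec,
    NetworkSpec,
    SimulationConfig,
    simulate_cohort,
    simulate_disease_cohort,
    simulate_network,
)

import networkx as nx


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def _bfs_lengths(adj: dict, source) -> dict:
    """Plain queue BFS, independent of networkx."""
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def harmonic_oracle(edges: list[tuple], nodes: list, genes: list) -> float:
    """Brute-force harmonic average distance from scratch (BFS per seed)."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    genes = sorted(set(genes))
    recip = 0.0
    n_pairs = 0
    for i, u in enumerate(genes):
        dist = _bfs_lengths(adj, u)
        for v in genes[i + 1 :]:
            n_pairs += 1
            d = dist.get(v, 0)
            if d > 0:
                recip += 1.0 / d
    return math.inf if recip == 0 else n_pairs / recip


def diamond_oracle(graph: nx.Graph, seeds, n_added: int) -> list[str]:
    """Exhaustive re-computation of the DIAMOnD addition sequence.

    Every round scores every candidate with a from-scratch hypergeometric
    tail built on log-factorials; independent of the package's scipy-based
    scoring path.
    """
    logfact = [0.0]
    for i in range(1, graph.number_of_nodes() + 1):
        logfact.append(logfact[-1] + math.log(i))

    def comb(n, k):
        if k < 0 or k > n:
            return -math.inf
        return logfact[n] - logfact[k] - logfact[n - k]

    def tail(k, ks, n_nodes, s):
        tot = 0.0
        for i in range(ks, min(k, s) + 1):
            tot += math.exp(comb(s, i) + comb(n_nodes - s, k - i) - comb(n_nodes, k))
        return min(tot, 1.0)

    members = set(seeds) & set(graph.nodes)
    n_nodes = graph.number_of_nodes()
    added = []
    for _ in range(n_added):
        cands = {w for m in members for w in graph.neighbors(m)} - members
        if not cands:
            break
        scored = []
        for w in sorted(cands):
            k = graph.degree(w)
            ks = sum(1 for u in graph.neighbors(w) if u in members)
            scored.append((tail(k, ks, n_nodes, len(members)), -ks, k, w))
        pmin = min(s[0] for s in scored)
        tied = [s for s in scored if s[0] <= pmin * (1 + 1e-9) + 1e-300]
        _, _, w = min((s[1], s[2], s[3]) for s in tied)
        members.add(w)
        added.append(w)
    return added


def cliques_oracle(graph: nx.Graph) -> set[frozenset]:
    """Maximal cliques by bitmask subset checking (graphs up to ~20 nodes)."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in graph.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    is_clique = bytearray(1 << n)
    is_clique[0] = 1
    for s in range(1, 1 << n):
        lsb = s & (-s)
        rest = s ^ lsb
        i = lsb.bit_length() - 1
        is_clique[s] = 1 if (is_clique[rest] and (adj[i] & rest) == rest) else 0
    out = set()
    full = (1 << n) - 1
    for s in range(1, 1 << n):
        if not is_clique[s]:
            continue
        # maximal iff no outside vertex adjacent to all of s
        maximal = True
        outside = full ^ s
        while outside:
            b = outside & (-outside)
            j = b.bit_length() - 1
            if (adj[j] & s) == s:
                maximal = False
                break
            outside ^= b
        if maximal:
            out.add(frozenset(nodes[i] for i in range(n) if s >> i & 1))
    return out


def fisher_oracle_margin(r: int, c: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p and FE per overlap, from log-factorials only."""
    logfact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])

    def lcomb(nn, kk):
        return logfact[nn] - logfact[kk] - logfact[nn - kk]

    lo = max(0, r + c - n)
    hi = min(r, c)
    support = np.arange(lo, hi + 1)
    logpmf = np.array([lcomb(c, a) + lcomb(n - c, r - a) - lcomb(n, r) for a in support])
    pmf = np.exp(logpmf)
    p = np.array([pmf[pmf <= pmf[i] * (1 + 1e-9)].sum() for i in range(len(support))])
    fe = (support / r) / (c / n)
    return fe, np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# criterion studies
# ---------------------------------------------------------------------------


def study_colocalization_oracle(n_graphs: int = 100, max_nodes: int = 30, seed: int = 0) -> dict:
    """Harmonic-average distance vs the brute-force BFS oracle on random graphs."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_graphs):
        n = int(rng.integers(5, max_nodes + 1))
        p = float(rng.uniform(0.1, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        k = int(rng.integers(2, max(3, n // 2)))
        genes = list(rng.choice(n, size=k, replace=False))
        h = harmonic_average_distance(g, genes)
        oracle = harmonic_oracle(list(g.edges), list(g.nodes), genes)
        if (math.isinf(h) and math.isinf(oracle)) or abs(h - oracle) < 1e-12:
            agree += 1
    return {"agree_fraction": agree / n_graphs, "n": n_graphs}


def study_diamond_oracle(n_graphs: int = 30, max_nodes: int = 25, seed: int = 0) -> dict:
    """DIAMOnD addition ranking vs exhaustive hypergeometric re-computation."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_graphs):
        n = int(rng.integers(8, max_nodes + 1))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.4)), seed=int(rng.integers(2**31)))
        g.add_edges_from(zip(range(n - 1), range(1, n)))  # ensure connected
        seeds = [int(s) for s in rng.choice(n, size=max(2, n // 5), replace=False)]
        n_added = int(rng.integers(1, max(2, n // 2)))
        res = run_diamond(PPINetwork(g, 0), seeds, n_added=n_added)
        ranked = sorted(res.scores, key=res.scores.get)
        if ranked == diamond_oracle(g, seeds, n_added):
            agree += 1
    return {"agree_fraction": agree / n_graphs, "n": n_graphs}


def study_clique_oracle(n_graphs: int = 50, max_nodes: int = 20, seed: int = 0) -> dict:
    """Maximal-clique enumeration vs the bitmask subset-checking oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_graphs):
        # a few graphs at the top size, the rest smaller for speed
        n = max_nodes if i % 10 == 0 else int(rng.integers(5, 17))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.6)), seed=int(rng.integers(2**31)))
        ours = set(enumerate_maximal_cliques(g))
        if ours == cliques_oracle(g):
            agree += 1
    return {"agree_fraction": agree / n_graphs, "n": n_graphs}


def study_fisher_oracle(max_n: int = 60) -> dict:
    """FE and two-sided Fisher p on every margin/overlap with N <= max_n.

    The implementation route is the vectorized hypergeometric scan (checked
    against the scipy ``fisher_exact`` single-table route on a subsample);
    the oracle rebuilds every probability from log-factorials.
    """
    n_checked = 0
    agree = 0
    spot = 0
    spot_agree = 0
    rng = np.random.default_rng(0)
    for n in range(4, max_n + 1):
        for r in range(1, n + 1):
            for c in range(1, n + 1):
                support, fe, p = fisher_margin_scan(r, c, n)
                fe_o, p_o = fisher_oracle_margin(r, c, n)
                ok = np.allclose(fe, fe_o, atol=1e-10) and np.allclose(p, p_o, atol=1e-9)
                n_checked += len(support)
                agree += len(support) if ok else int(np.sum(np.isclose(p, p_o, atol=1e-9)))
                if rng.random() < 0.001:
                    a = int(support[rng.integers(len(support))])
                    b, cc, d = r - a, c - a, n - r - c + a
                    if a + b > 0 and a + cc > 0 and d >= 0:
                        fe_s, p_s = fisher_table(a, b, cc, d)
                        spot += 1
                        spot_agree += int(
                            math.isclose(p_s, p[support == a][0], rel_tol=1e-7, abs_tol=1e-12)
                            and math.isclose(fe_s, fe[support == a][0], rel_tol=1e-12)
                        )
    return {
        "agree_fraction": agree / n_checked,
        "n": n_checked,
        "scipy_spot_agree_fraction": (spot_agree / spot) if spot else 1.0,
        "n_spot": spot,
    }


def study_null_calibration(n_probes: int = 2000, seed: int = 0) -> dict:
    """No planted effects, 12/12 samples: p-values uniform, ~0 DMPs."""
    cfg = SimulationConfig(
        n_probes=n_probes,
        n_genes=max(50, n_probes // 10),
        seed=seed,
        effects=(),
        groups=(("NP", 12, (0.6, 0.4)), ("T2", 12, (0.45, 0.55))),
    )
    ds, _ = simulate_cohort(cfg)
    dec = reffree_decompose(ds.betas, 2, seed=seed, n_restarts=3)
    fit = fit_probe_models(beta_to_m(ds.betas), build_design(ds.samples, dec.omega))
    tab = fit.xs("T2_vs_NP", level="contrast")
    db = compute_delta_beta(ds.betas, ds.samples["group"], ("NP", "T2"))
    called = call_dmps(tab, db)
    ks = sstats.kstest(tab["p"].to_numpy(), "uniform")
    return {
        "ks_p": float(ks.pvalue),
        "frac_p_below_05": float((tab["p"] < 0.05).mean()),
        "n_dmps": int(called["is_dmp"].sum()),
        "n": n_probes,
    }


def study_coloc_null_uniformity(
    n_runs: int = 200, n_perm: int = 60, n_nodes: int = 200, n_seeds: int = 10, seed: int = 0
) -> dict:
    """Permutation p under uniformly random seed sets is uniform."""
    from .synth import preferential_attachment_edges

    rng = np.random.default_rng(seed)
    g = nx.Graph(preferential_attachment_edges(n_nodes, 2, rng))
    net = PPINetwork(g, 0)
    ps = [
        colocalization_test(
            net,
            [int(x) for x in rng.choice(n_nodes, size=n_seeds, replace=False)],
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        ).p
        for _ in range(n_runs)
    ]
    ks = sstats.kstest(ps, "uniform")
    return {"ks_p": float(ks.pvalue), "n": n_runs}


def study_deconv_recovery(n_probes: int = 1500, seed: int = 0) -> dict:
    """Omega recovery: Pearson r vs measured fractions and MAE vs truth."""
    cfg = SimulationConfig(n_probes=n_probes, n_genes=max(50, n_probes // 10), seed=seed)
    ds, truth = simulate_cohort(cfg)
    dec = reffree_decompose(ds.betas, 2, seed=0, n_restarts=3)
    mae = min(
        float(np.abs(dec.omega.to_numpy()[:, list(p)] - truth.omega.to_numpy()).mean())
        for p in itertools.permutations(range(2))
    )
    r, _ = validate_against_reference(dec.omega.iloc[:, 1], ds.samples["memory_fraction"])
    return {"pearson_r": abs(float(r)), "omega_mae": mae, "n": int(ds.n_samples)}


def study_k_selection(n_seeds: int = 10, n_probes: int = 800, seed: int = 0) -> dict:
    """Fraction of two-type cohorts for which K=2 is selected."""
    hits = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_probes=n_probes, n_genes=max(50, n_probes // 10), seed=seed + 100 + i, effects=()
        )
        ds, _ = simulate_cohort(cfg)
        ks = select_k(ds.betas, k_range=[1, 2, 3], n_boot=8, seed=seed + i, n_restarts=2)
        hits += ks.selected_k == 2
    return {"k2_fraction": hits / n_seeds, "n": n_seeds}


def study_dmp_sensitivity(n_seeds: int = 5, n_probes: int = 4000, seed: int = 0) -> dict:
    """Recovery of planted |delta beta| = 0.10 probes at n = 12/group."""
    sens = []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_probes=n_probes,
            n_genes=max(100, n_probes // 10),
            seed=seed + i,
            effects=(EffectSpec(group="T2", n_probes=100, delta_beta=(0.10, 0.10)),),
        )
        ds, truth = simulate_cohort(cfg)
        norm = bmiq_normalize(ds)
        dec = reffree_decompose(norm.betas, 2, seed=0, n_restarts=3)
        fit = fit_probe_models(beta_to_m(norm.betas), build_design(norm.samples, dec.omega))
        tab = fit.xs("T2_vs_NP", level="contrast")
        db = compute_delta_beta(norm.betas, norm.samples["group"], ("NP", "T2"))
        called = call_dmps(tab, db)
        planted = set(truth.effect_table("T2").index)
        hit = set(called.index[called["is_dmp"]])
        sens.append(len(planted & hit) / len(planted))
    return {"sensitivity": float(np.mean(sens)), "per_seed": sens, "n": n_seeds}


def study_module_recovery(n_seeds: int = 5, seed: int = 0) -> dict:
    """Planted 5-clique module recovered by MCODE and the consensus."""
    mcode_hits = 0
    consensus_hits = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_probes=1000, n_genes=100, seed=seed + i, network=NetworkSpec(n_nodes=200, module_size=5)
        )
        _, truth = simulate_cohort(cfg)
        net, net_truth = simulate_network(cfg, truth)
        seeds_list = [g for g in truth.effect_genes if g in net.nodes]
        results = [
            run_mcode(net, seeds_list),
            run_diamond(net, seeds_list, n_added=20),
            run_clique_sum(net, seeds_list),
            run_correlation_clique(
                net, seeds_list, {s: 1.0 for s in seeds_list}, n_iter=30, rng_seed=seed + i
            ),
        ]
        consensus = build_consensus(results)
        planted = set(net_truth.module_genes)
        mcode_hits += planted <= results[0].genes
        consensus_hits += planted <= consensus.genes
    return {
        "mcode_fraction": mcode_hits / n_seeds,
        "consensus_fraction": consensus_hits / n_seeds,
        "n": n_seeds,
    }


def study_vista_recovery(n_seeds: int = 20, n_probes: int = 2000, seed: int = 0) -> dict:
    """Planted case-like controls removed exactly by the divisive selection."""
    exact = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(n_probes=n_probes, n_genes=max(50, n_probes // 10), seed=seed + i)
        _, truth = simulate_cohort(cfg)
        ddata, dtruth = simulate_disease_cohort(cfg, truth)
        sel = vista_subgroups(ddata, max_removed_fraction=0.6)
        exact += sorted(sel.removed_ids) == sorted(dtruth.overlap_controls)
    return {"exact_fraction": exact / n_seeds, "n": n_seeds}


def endtoend_disease_signs(
    seed: int,
    n_probes: int = 2000,
    signs: tuple[int, ...] = (-1, -1, 1),
    run_bmiq: bool = True,
) -> dict:
    """One end-to-end run: cohort -> module CpGs -> per-disease correlation sign.

    Returns the per-disease Pearson r, p and sign together with the planted
    signs (the analogue of diseases that improve versus worsen in pregnancy).
    """
    cfg = SimulationConfig(
        n_probes=n_probes,
        n_genes=max(100, n_probes // 10),
        seed=seed,
        network=NetworkSpec(n_nodes=200),
    )
    ds, truth = simulate_cohort(cfg)
    filtered, _ = filter_probes(ds)
    if run_bmiq:
        filtered = bmiq_normalize(filtered)
    dec = reffree_decompose(filtered.betas, 2, seed=seed, n_restarts=3)
    fit = fit_probe_models(beta_to_m(filtered.betas), build_design(filtered.samples, dec.omega))
    tab = fit.xs("T2_vs_NP", level="contrast")
    db = compute_delta_beta(filtered.betas, filtered.samples["group"], ("NP", "T2"))
    preg = call_dmps(tab, db)
    dmgs = map_dmps_to_genes(preg, filtered.annotation)

    net, _ = simulate_network(cfg, truth)
    seeds_list = sorted(set(dmgs.index) & net.nodes)
    results = [
        run_mcode(net, seeds_list),
        run_diamond(net, seeds_list, n_added=20),
        run_clique_sum(net, seeds_list),
        run_correlation_clique(
            net, seeds_list, {s: 1.0 for s in seeds_list}, n_iter=30, rng_seed=seed
        ),
    ]
    consensus = build_consensus(results)
    module_cpgs = module_to_cpgs(consensus.genes, filtered.annotation, preg)

    out = {"planted_signs": list(signs), "diseases": []}
    for di, sign in enumerate(signs):
        spec = DiseaseSpec(effect_sign=sign)
        ddata, _ = simulate_disease_cohort(cfg, truth, disease=spec, seed_offset=di + 1)
        sel = vista_subgroups(ddata, max_removed_fraction=0.6)
        sub = ddata.subset_samples(sel.retained_controls + sel.retained_cases)
        ddec = reffree_decompose(sub.betas, 2, seed=seed, n_restarts=3)
        dfit = fit_probe_models(
            beta_to_m(sub.betas),
            build_design(sub.samples, ddec.omega, reference_group="control"),
        )
        dstats = dfit.xs("case_vs_control", level="contrast")
        ddb = compute_delta_beta(sub.betas, sub.samples["group"], ("control", "case"))
        dtable = call_dmps(dstats, ddb)
        disease_dmps = dtable.index[dtable["is_dmp"]]
        entry = {"planted_sign": sign, "n_dmps": int(len(disease_dmps))}
        try:
            enr = cpg_enrichment(module_cpgs.index, disease_dmps, filtered.betas.index)
            entry["fold_enrichment"] = enr.fold_enrichment
            entry["enrichment_p"] = enr.p
            corr = direction_correlation(
                module_cpgs["delta_beta"], dtable["delta_beta"], enr.overlap_ids
            )
            entry.update(corr.to_dict())
        except ValueError as exc:
            entry["error"] = str(exc)
        out["diseases"].append(entry)
    return out


def study_directionality(n_seeds: int = 20, seed: int = 0, n_probes: int = 2000) -> dict:
    """Fraction of end-to-end runs with all three signs recovered at p < 0.05."""
    hits = 0
    runs = []
    for i in range(n_seeds):
        res = endtoend_disease_signs(seed=seed + i, n_probes=n_probes)
        ok = all(
            "sign" in d and d["sign"] == d["planted_sign"] and d["pearson_p"] < 0.05
            for d in res["diseases"]
        )
        hits += ok
        runs.append(ok)
    return {"sign_fraction": hits / n_seeds, "per_seed": runs, "n": n_seeds}
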