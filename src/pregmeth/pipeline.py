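"""End-to-end orchestration: simulate -> preprocess -> deconvolve -> DMPs ->
module -> disease, with every intermediate table written to a run directory.

The pipeline is deterministic under a fixed master seed: all stage seeds are
derived from it, and two runs with the same config produce byte-identical
summary JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconv import reffree_decompose, select_k, validate_against_reference
from .diffmeth import (
    build_design,
    call_dmps,
    compute_delta_beta,
    fit_probe_models,
    map_dmps_to_genes,
    mds_coordinates,
)
from .disease import (
    DMCriterion,
    cpg_enrichment,
    direction_correlation,
    geneset_enrichment,
    vista_subgroups,
)
from .netmodule import (
    build_consensus,
    colocalization_test,
    export_sif,
    module_to_cpgs,
    run_clique_sum,
    run_correlation_clique,
    run_diamond,
    run_mcode,
)
from .preprocess import (
    FilterThresholds,
    MethylationDataset,
    beta_to_m,
    bmiq_normalize,
    filter_probes,
)
from .synth import (
    DiseaseSpec,
    SimulationConfig,
    simulate_cohort,
    simulate_disease_cohort,
    simulate_network,
    write_cohort,
    write_gmt,
    write_network,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Every threshold and constant of the pipeline in one block."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    run_bmiq: bool = True
    logit_eps: float = 1e-3
    k_range: tuple[int, ...] = (1, 2, 3)
    n_boot: int = 8
    n_restarts: int = 3
    q_thresh: float = 0.05
    db_thresh: float = 0.05
    pregnancy_contrast: str = "T2_vs_NP"
    min_score: int = 900
    n_perm: int = 300
    mcode_vwp: float = 0.2
    diamond_n_added: int = 20
    clique_min_size: int = 3
    clique_alpha: float = 0.05
    corr_clique_iter: int = 30
    corr_clique_cutoff: float = 0.5
    min_methods: int = 3
    vista_max_removed_fraction: float = 0.5
    vista_removable: str = "controls"
    diseases: tuple[DiseaseSpec, ...] = (
        DiseaseSpec(effect_sign=-1),  # improves (MS-like)
        DiseaseSpec(effect_sign=-1),  # improves (RA-like)
        DiseaseSpec(effect_sign=+1),  # worsens (SLE-like)
    )
    disease_names: tuple[str, ...] = ("disease_neg_a", "disease_neg_b", "disease_pos")
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.min_methods <= 4:
            raise ConfigError("min_methods must lie in [1, 4]")
        if not set(self.k_range) <= set(range(1, 11)):
            raise ConfigError("k_range must lie within [1, 10]")
        if not (0 < self.q_thresh < 1 and 0 <= self.db_thresh < 1):
            raise ConfigError("thresholds out of range")
        if len(self.diseases) != len(self.disease_names):
            raise ConfigError("diseases and disease_names must align")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimulationConfig(**kwargs["sim"])
        if "filters" in kwargs:
            kwargs["filters"] = FilterThresholds(**kwargs["filters"])
        if "diseases" in kwargs:
            kwargs["diseases"] = tuple(DiseaseSpec(**d) for d in kwargs["diseases"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def param_hash(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage on a synthetic design and write all artifacts.

    Returns the summary dict (also written as ``summary.json``): module size
    and provenance split, co-localization stats, and per-disease fold
    enrichment, correlation and sign.
    """
    config.validate()
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)

    # --- simulate ---------------------------------------------------------
    dataset, truth = simulate_cohort(sim)
    write_cohort(dataset, truth, out / "simulated")
    network, net_truth = simulate_network(sim, truth)
    write_network(network, out / "network_edges.tsv")
    write_gmt({"planted_module": net_truth.module_genes}, out / "gene_sets.gmt")

    # --- preprocess -------------------------------------------------------
    filtered, report = filter_probes(dataset, config.filters)
    pd.DataFrame(report.to_frame()).to_csv(out / "filter_report.tsv", sep="\t", index=False)
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    if config.run_bmiq:
        filtered = bmiq_normalize(filtered)
    filtered.betas.to_csv(out / "betas_normalized.tsv", sep="\t")

    # --- deconvolution ----------------------------------------------------
    ks = select_k(
        filtered.betas,
        k_range=config.k_range,
        n_boot=config.n_boot,
        seed=config.seed,
        n_restarts=config.n_restarts,
    )
    ks.table.to_csv(out / "k_selection.tsv", sep="\t")
    decomp = ks.fits[ks.selected_k]
    decomp.omega.to_csv(out / "omega.tsv", sep="\t")
    decomp.mu.to_csv(out / "mu.tsv", sep="\t")
    omega_r = np.nan
    if "memory_fraction" in filtered.samples.columns and decomp.k >= 2:
        # align the inferred column with the measured fraction by correlation
        rs = [
            validate_against_reference(decomp.omega[c], filtered.samples["memory_fraction"])[0]
            for c in decomp.omega.columns
        ]
        omega_r = float(max(np.abs(rs)))

    # --- differential methylation ----------------------------------------
    m = beta_to_m(filtered.betas, eps=config.logit_eps)
    design = build_design(filtered.samples, decomp.omega if decomp.k > 1 else None)
    fit = fit_probe_models(m, design)
    groups = filtered.samples["group"]
    dmp_tables = {}
    for label in sorted(fit.index.get_level_values("contrast").unique()):
        g2, _, g1 = label.partition("_vs_")
        stats_c = fit.xs(label, level="contrast")
        db = compute_delta_beta(filtered.betas, groups, (g1, g2))
        dmp_tables[label] = call_dmps(stats_c, db, config.q_thresh, config.db_thresh)
        dmp_tables[label].to_csv(out / f"dmp_{label}.tsv", sep="\t")
    preg = dmp_tables[config.pregnancy_contrast]
    dmgs = map_dmps_to_genes(preg, filtered.annotation)
    dmgs.to_csv(out / "dmg_pregnancy.tsv", sep="\t")
    coords, varexp = mds_coordinates(filtered.betas)
    coords.to_csv(out / "mds_coordinates.tsv", sep="\t")
    summary_mds = [round(float(v), 6) for v in varexp]

    # --- module identification -------------------------------------------
    seeds = sorted(set(dmgs.index) & network.nodes)
    summary: dict = {
        "seed": config.seed,
        "n_probes_retained": report.retained,
        "n_dmps_pregnancy": int(preg["is_dmp"].sum()),
        "n_dmgs_pregnancy": int(len(dmgs)),
        "selected_k": ks.selected_k,
        "omega_reference_r": omega_r,
        "mds_variance_explained": summary_mds,
    }
    if len(seeds) >= 2:
        coloc = colocalization_test(network, seeds, n_perm=config.n_perm, seed=config.seed)
        (out / "colocalization.json").write_text(json.dumps(coloc.to_dict(), indent=1))
        summary["colocalization"] = coloc.to_dict()
        seed_scores = {
            g: max(1e-6, 1.0 - float(dmgs.loc[g, "min_q"])) for g in seeds
        }
        results = [
            run_mcode(network, seeds, vwp=config.mcode_vwp),
            run_diamond(network, seeds, n_added=config.diamond_n_added),
            run_clique_sum(
                network, seeds, min_clique_size=config.clique_min_size, alpha=config.clique_alpha
            ),
            run_correlation_clique(
                network,
                seeds,
                seed_scores,
                n_iter=config.corr_clique_iter,
                freq_cutoff=config.corr_clique_cutoff,
                rng_seed=config.seed,
            ),
        ]
        for r in results:
            pd.Series(sorted(r.genes), name="gene").to_csv(
                out / f"module_{r.method}.tsv", sep="\t", index=False
            )
        consensus = build_consensus(
            results, config.min_methods, dmg_directions=dict(dmgs["direction"])
        )
        consensus.to_frame().to_csv(out / "module_consensus.tsv", sep="\t")
        export_sif(network, consensus.genes, out / "module_consensus.sif")
        module_cpgs = module_to_cpgs(consensus.genes, filtered.annotation, preg)
        module_cpgs.to_csv(out / "module_cpgs.tsv", sep="\t")
        n_seed_origin, n_net = consensus.provenance_split()
        summary["module"] = {
            "n_genes": len(consensus.genes),
            "n_seed_origin": n_seed_origin,
            "n_network_derived": n_net,
            "per_method_sizes": {r.method: len(r.genes) for r in results},
            "n_module_cpgs": int(len(module_cpgs)),
        }
    else:
        consensus = None
        module_cpgs = pd.DataFrame(columns=["genes", "delta_beta", "is_dmp"])
        summary["module"] = {"n_genes": 0, "note": "fewer than 2 seed genes in network"}

    # --- disease analyses -------------------------------------------------
    summary["diseases"] = {}
    vista_criterion = DMCriterion(config.q_thresh, config.db_thresh)
    for di, (name, spec) in enumerate(zip(config.disease_names, config.diseases)):
        ddata, dtruth = simulate_disease_cohort(sim, truth, disease=spec, seed_offset=di + 1)
        sel = vista_subgroups(
            ddata,
            case_label=spec.case_label,
            control_label=spec.control_label,
            dm_criterion=vista_criterion,
            max_removed_fraction=config.vista_max_removed_fraction,
            removable=config.vista_removable,
        )
        sub = ddata.subset_samples(sel.retained_controls + sel.retained_cases)
        dm = beta_to_m(sub.betas, eps=config.logit_eps)
        ddec = reffree_decompose(sub.betas, max(2, decomp.k), seed=config.seed, n_restarts=config.n_restarts)
        ddesign = build_design(sub.samples, ddec.omega, reference_group=spec.control_label)
        dfit = fit_probe_models(dm, ddesign)
        label = f"{spec.case_label}_vs_{spec.control_label}"
        dstats = dfit.xs(label, level="contrast")
        ddb = compute_delta_beta(sub.betas, sub.samples["group"], (spec.control_label, spec.case_label))
        dtable = call_dmps(dstats, ddb, config.q_thresh, config.db_thresh)
        dtable.to_csv(out / f"dmp_{name}.tsv", sep="\t")
        disease_dmps = dtable.index[dtable["is_dmp"]]
        entry: dict = {
            "planted_sign": spec.effect_sign,
            "n_dmps": int(len(disease_dmps)),
            "n_controls_removed": len(sel.removed),
        }
        if len(disease_dmps) and len(module_cpgs):
            enr = cpg_enrichment(module_cpgs.index, disease_dmps, filtered.betas.index)
            entry["cpg_enrichment"] = enr.to_dict()
            if len(enr.overlap_ids) >= 3:
                corr = direction_correlation(
                    module_cpgs["delta_beta"], dtable["delta_beta"], enr.overlap_ids
                )
                entry["directionality"] = corr.to_dict()
            ddmgs = map_dmps_to_genes(dtable, ddata.annotation)
            if len(ddmgs) and truth.effect_genes:
                gene_bg = sorted(set(truth.probe_gene_map.unique()))
                try:
                    genr = geneset_enrichment(set(ddmgs.index), set(truth.effect_genes), gene_bg)
                    entry["gene_enrichment"] = genr.to_dict()
                except ValueError:
                    pass
        summary["diseases"][name] = entry

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "config": _as_jsonable(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(_as_jsonable(summary), indent=1, sort_keys=True))
    return summary
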