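"""Disease relevance of the module: subgroup selection, enrichment, direction.

For each disease cohort: the divisive subgroup selection strips the
case-like controls, DMPs are called between the retained groups through the
deconvolution-adjusted model, the module CpGs are tested for enrichment in
the disease DMPs, and the paired pregnancy/disease effects on the
overlapping CpGs are correlated.  The sign pattern of those correlations is
the study's directionality verdict.  Writes results/06_disease/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DISEASES, RESULTS, SEED, load_dataset  # noqa: E402

import pregmeth as pm  # noqa: E402


def main() -> None:
    module_cpgs = pd.read_csv(RESULTS / "05_module" / "module_cpgs.tsv", sep="\t", index_col=0)
    background = pd.read_csv(
        RESULTS / "02_preprocessed" / "betas.tsv", sep="\t", index_col=0, usecols=[0]
    ).index
    out = RESULTS / "06_disease"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    verdicts = {}
    for name in DISEASES:
        ddata = load_dataset(RESULTS / "01_simulated" / name)
        truth = json.loads((RESULTS / "01_simulated" / name / "truth.json").read_text())
        sel = pm.vista_subgroups(ddata, max_removed_fraction=0.6, seed=SEED)
        sub = ddata.subset_samples(sel.retained_controls + sel.retained_cases)
        dec = pm.reffree_decompose(sub.betas, 2, seed=SEED, n_restarts=3)
        fit = pm.fit_probe_models(
            pm.beta_to_m(sub.betas),
            pm.build_design(sub.samples, dec.omega, reference_group="control"),
        )
        db = pm.compute_delta_beta(sub.betas, sub.samples["group"], ("control", "case"))
        table = pm.call_dmps(fit.xs("case_vs_control", level="contrast"), db)
        table.to_csv(out / f"dmp_{name}.tsv", sep="\t")
        dmps = table.index[table["is_dmp"]]
        enr = pm.cpg_enrichment(module_cpgs.index, dmps, background)
        corr = pm.direction_correlation(
            module_cpgs["delta_beta"], table["delta_beta"], enr.overlap_ids
        )
        verdicts[name] = corr.sign
        rows.append(
            {
                "disease": name,
                "removed_controls": ",".join(sel.removed_ids),
                "planted_overlap": ",".join(truth["overlap_controls"]),
                "n_dmps": len(dmps),
                "FE": enr.fold_enrichment,
                "enrichment_p": enr.p,
                "n_overlap": len(enr.overlap_ids),
                "pearson_r": corr.pearson_r,
                "pearson_p": corr.pearson_p,
                "spearman_rho": corr.spearman_rho,
                "spearman_p": corr.spearman_p,
                "sign": corr.sign,
            }
        )
        print(
            f"{name}: removed {len(sel.removed_ids)} controls "
            f"(planted {len(truth['overlap_controls'])}); {len(dmps)} DMPs; module CpG "
            f"enrichment FE={enr.fold_enrichment:.2f} (p={enr.p:.2g}); direction "
            f"r={corr.pearson_r:+.2f} (p={corr.pearson_p:.2g}), rho={corr.spearman_rho:+.2f}"
        )
    pd.DataFrame(rows).to_csv(out / "disease_summary.tsv", sep="\t", index=False)
    (out / "directionality_verdicts.json").write_text(json.dumps(verdicts, indent=1))
    planted = [s.effect_sign for s in DISEASES.values()]
    print(
        f"sign pattern {list(verdicts.values())} vs planted {planted}: "
        f"{'match' if list(verdicts.values()) == planted else 'MISMATCH'}"
    )


if __name__ == "__main__":
    main()
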