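"""Deconvolution-adjusted differential methylation for the three contrasts.

Fits the moderated linear model on M-values with the omega proportions as
adjustment covariates, calls DMPs at FDR < 0.05 and |delta beta| > 0.05,
maps them to genes (majority direction), and computes the classical MDS of
the normalized betas.  Writes the DMP/DMG tables under results/04_diffmeth/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_dataset  # noqa: E402

import pregmeth as pm  # noqa: E402


def main() -> None:
    dataset = load_dataset(RESULTS / "02_preprocessed")
    omega = pd.read_csv(RESULTS / "03_deconvolution" / "omega.tsv", sep="\t", index_col=0)
    design = pm.build_design(dataset.samples, omega)
    fit = pm.fit_probe_models(pm.beta_to_m(dataset.betas), design)
    out = RESULTS / "04_diffmeth"
    out.mkdir(parents=True, exist_ok=True)
    groups = dataset.samples["group"]
    lines = []
    for label in ("T1_vs_NP", "T2_vs_NP", "T2_vs_T1"):
        g2, _, g1 = label.partition("_vs_")
        db = pm.compute_delta_beta(dataset.betas, groups, (g1, g2))
        table = pm.call_dmps(fit.xs(label, level="contrast"), db)
        table.to_csv(out / f"dmp_{label}.tsv", sep="\t")
        n = int(table["is_dmp"].sum())
        hyper = int((table["is_dmp"] & (table["direction"] == "hyper")).sum())
        lines.append(f"{label}: {n} DMPs ({hyper} hyper / {n - hyper} hypo)")
        if label == "T2_vs_NP":
            dmgs = pm.map_dmps_to_genes(table, dataset.annotation)
            dmgs.to_csv(out / "dmg_T2_vs_NP.tsv", sep="\t")
            lines[-1] += f", {len(dmgs)} DMGs"
    coords, varexp = pm.mds_coordinates(dataset.betas)
    coords.to_csv(out / "mds_coordinates.tsv", sep="\t")
    lines.append(
        "MDS variance explained: " + ", ".join(f"{v:.1%}" for v in varexp[:3]) + " (first three)"
    )
    print("; ".join(lines))


if __name__ == "__main__":
    main()
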