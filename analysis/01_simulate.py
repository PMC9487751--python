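"""Generate the synthetic study: cohort, PPI network and disease cohorts.

Writes the beta matrix, sample sheet, probe annotation, STRING-dialect edge
list and the full ground truth under results/01_simulated/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DISEASES, RESULTS, SIM  # noqa: E402

import pregmeth as pm  # noqa: E402


def main() -> None:
    out = RESULTS / "01_simulated"
    dataset, truth = pm.simulate_cohort(SIM)
    pm.synth.write_cohort(dataset, truth, out)
    network, net_truth = pm.simulate_network(SIM, truth)
    pm.synth.write_network(network, out / "network_edges.tsv")
    pm.synth.write_gmt(
        {"planted_module": net_truth.module_genes, "effect_genes": truth.effect_genes},
        out / "gene_sets.gmt",
    )
    (out / "network_truth.json").write_text(
        json.dumps({"module_genes": net_truth.module_genes}, indent=1)
    )
    for name, spec in DISEASES.items():
        ddata, dtruth = pm.simulate_disease_cohort(
            SIM, truth, disease=spec, seed_offset=list(DISEASES).index(name) + 1
        )
        pm.synth.write_cohort(ddata, dtruth, out / name)
    print(
        f"simulated {dataset.n_probes} probes x {dataset.n_samples} samples "
        f"({dataset.samples['group'].value_counts().to_dict()}), "
        f"{network.n_edges} PPI edges, planted module {net_truth.module_genes}, "
        f"{len(DISEASES)} disease cohorts with signs "
        f"{[s.effect_sign for s in DISEASES.values()]}"
    )


if __name__ == "__main__":
    main()
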