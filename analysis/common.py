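"""Shared study configuration for the numbered analysis drivers.

The drivers run the full chain on one synthetic study: a pregnancy-style
cohort (12 non-pregnant / 11 first-trimester / 12 second-trimester samples,
two latent cell types), a scale-free PPI network with a planted dense
module on the effect genes, and three disease cohorts whose planted effect
signs are (-1, -1, +1) relative to the pregnancy effects — the analogue of
two diseases that improve during pregnancy and one that worsens.

Each driver reads the previous driver's outputs from ``results/`` and is a
thin narrative layer; all computation lives in the ``pregmeth`` package.
"""

from __future__ import annotations

import pathlib

import pregmeth as pm

SEED = 1
RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"

SIM = pm.SimulationConfig(
    n_probes=2000,
    n_genes=200,
    seed=SEED,
    network=pm.NetworkSpec(n_nodes=200),
)

DISEASES = {
    "disease_improving_a": pm.DiseaseSpec(effect_sign=-1),
    "disease_improving_b": pm.DiseaseSpec(effect_sign=-1),
    "disease_worsening": pm.DiseaseSpec(effect_sign=+1),
}


def load_dataset(stage_dir: pathlib.Path) -> pm.MethylationDataset:
    import pandas as pd

    return pm.MethylationDataset(
        betas=pd.read_csv(stage_dir / "betas.tsv", sep="\t", index_col=0),
        samples=pd.read_csv(stage_dir / "samples.csv", index_col=0),
        annotation=pd.read_csv(stage_dir / "annotation.tsv", sep="\t", index_col=0),
    )
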