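"""Synthetic cohorts, networks and disease datasets with known ground truth.

The generator emulates the statistical structure a CpG methylation study of
sorted CD4+ T cells assumes: bimodal beta values, two latent cell types
(naive / memory) whose mixing proportions shift between groups, planted
group effects of 5-15% delta-beta, probe-level QC artifacts, a scale-free
PPI network with a planted dense module overlapping the effect genes, and
disease cohorts containing a non-separable case-like subgroup of controls
whose effect sign relative to the pregnancy effects is configurable.

Every planted signal is recorded in a :class:`GroundTruth` so downstream
operations can be verified against the generating process.  All randomness
flows from a single integer seed through ``numpy``'s seed-spawning scheme.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netmodule import PPINetwork, build_network
from .preprocess import MethylationDataset

#: canonical group labels of the default pregnancy design
DEFAULT_GROUPS = (
    ("NP", 12, (0.60, 0.40)),
    ("T1", 11, (0.55, 0.45)),
    ("T2", 12, (0.45, 0.55)),
)

ARTIFACT_FILTERS = ("detection_p", "bead_count", "no_cpg", "snp_proximity", "multi_mapping")


@dataclass
class GroupSpec:
    label: str
    n_samples: int
    mean_props: tuple[float, ...]

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("group sample count must be positive")
        props = np.asarray(self.mean_props, float)
        if (props < 0).any() or (props > 1).any() or abs(props.sum() - 1) > 1e-8:
            raise ValueError(f"mixing proportions of {self.label} must lie on the simplex")


@dataclass
class EffectSpec:
    """Planted group effect: ``n_probes`` probes shifted in group ``group``.

    ``delta_beta`` is the magnitude range of the planted mean beta shift
    relative to the reference group (drawn uniformly); ``frac_hyper`` is the
    fraction of planted probes gaining methylation.
    """

    group: str
    n_probes: int
    delta_beta: tuple[float, float] = (0.05, 0.15)
    frac_hyper: float = 0.67
    cell_types: str | int = "all"  # "all" shifts the mixture mean; int shifts one profile

    def __post_init__(self):
        lo, hi = self.delta_beta
        if not (0 < lo <= hi < 0.5):
            raise ValueError("effect delta beta must lie in (0, 0.5)")


@dataclass
class NetworkSpec:
    n_nodes: int = 300
    m: int = 2
    module_size: int = 8
    planted_clique: bool = True
    score_threshold: int = 900
    module_score: int = 990


@dataclass
class DiseaseSpec:
    n_cases: int = 15
    n_controls: int = 10
    overlap_fraction: float = 0.3
    effect_sign: int = -1
    n_shared_probes: int | None = None  # None: all pregnancy effect probes
    effect_scale: float = 1.0
    case_label: str = "case"
    control_label: str = "control"

    def __post_init__(self):
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap fraction must lie in [0, 1)")
        if self.effect_sign not in (-1, 1):
            raise ValueError("effect sign must be +1 or -1")


@dataclass
class SimulationConfig:
    """All generator knobs; defaults mirror the study-scale design."""

    n_probes: int = 5000
    n_genes: int = 500
    probes_per_gene_mean: float = 9.0
    groups: tuple = DEFAULT_GROUPS
    k_true: int = 2
    effects: tuple[EffectSpec, ...] = (EffectSpec(group="T2", n_probes=100),)
    n_effect_genes: int = 40
    noise_precision: float = 100.0
    omega_concentration: float = 6.0
    differing_fraction: float = 0.3
    qc_artifact_rates: dict = field(
        default_factory=lambda: {
            "detection_p": 0.008,
            "bead_count": 0.003,
            "no_cpg": 0.006,
            "snp_proximity": 0.02,
            "multi_mapping": 0.001,
        }
    )
    frac_type2: float = 0.6
    network: NetworkSpec = field(default_factory=NetworkSpec)
    disease: DiseaseSpec = field(default_factory=DiseaseSpec)
    reference_group: str | None = None  # default: first group
    seed: int = 0

    def __post_init__(self):
        if self.n_probes <= 0 or self.n_genes <= 0 or self.k_true <= 0:
            raise ValueError("counts must be positive")
        self.groups = tuple(
            g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in self.groups
        )
        for g in self.groups:
            if len(g.mean_props) != self.k_true:
                raise ValueError(
                    f"group {g.label} has {len(g.mean_props)} mixing proportions "
                    f"but k_true={self.k_true}"
                )
        labels = [g.label for g in self.groups]
        if self.reference_group is None:
            self.reference_group = labels[0]
        for e in self.effects:
            if e.group not in labels:
                raise ValueError(f"effect group {e.group} not among groups {labels}")


@dataclass
class GroundTruth:
    """Bookkeeping of every planted signal."""

    omega: pd.DataFrame | None = None
    mu: pd.DataFrame | None = None
    effects: pd.DataFrame | None = None  # probe_id, group, delta_beta (vs reference)
    differing_probes: list[str] = field(default_factory=list)
    artifact_probes: dict[str, list[str]] = field(default_factory=dict)
    probe_gene_map: pd.Series | None = None
    effect_genes: list[str] = field(default_factory=list)
    module_genes: list[str] = field(default_factory=list)
    overlap_controls: list[str] = field(default_factory=list)
    reference_group: str | None = None

    def effect_table(self, group: str) -> pd.Series:
        """Signed planted delta beta (group vs reference) indexed by probe."""
        if self.effects is None or self.effects.empty:
            return pd.Series(dtype=float)
        sub = self.effects[self.effects["group"] == group]
        return sub.set_index("probe_id")["delta_beta"]

    def to_json(self, path) -> None:
        payload = {
            "differing_probes": self.differing_probes,
            "artifact_probes": self.artifact_probes,
            "effect_genes": self.effect_genes,
            "module_genes": self.module_genes,
            "overlap_controls": self.overlap_controls,
            "reference_group": self.reference_group,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _logit(x):
    return np.log(x / (1.0 - x))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# cell-type methylomes
# ---------------------------------------------------------------------------


def simulate_profiles(
    n_probes: int,
    k_true: int,
    seed: int = 0,
    differing_fraction: float = 0.3,
) -> tuple[np.ndarray, list[int]]:
    """Latent cell-type methylomes drawn from a 3-state beta mixture.

    Returns the (n_probes x k_true) profile matrix and the indices of the
    planted differing probes.  Non-differing probes are identical across
    cell types; differing probes are shifted by at least 0.25 in the
    non-reference cell types, so they differ by >= 0.2 by construction.
    All entries are clipped to [0.01, 0.99].
    """
    if n_probes < 10 or k_true < 1:
        raise ValueError("need n_probes >= 10 and k_true >= 1")
    rng = np.random.default_rng(seed)
    state = rng.choice(3, size=n_probes, p=[0.45, 0.10, 0.45])
    a = np.array([5.0, 10.0, 45.0])[state]
    b = np.array([45.0, 10.0, 5.0])[state]
    base = np.clip(rng.beta(a, b), 0.01, 0.99)
    mu = np.tile(base[:, None], (1, k_true))
    differing: list[int] = []
    if k_true > 1 and differing_fraction > 0:
        n_diff = int(math.floor(differing_fraction * n_probes))
        differing = sorted(rng.choice(n_probes, size=n_diff, replace=False).tolist())
        for k in range(1, k_true):
            # cell-type-specific CpGs switch state (often nearly fully): draw
            # shifts in [0.3, 0.9]; clipping keeps the realized gap >= 0.3
            delta = rng.uniform(0.3, 0.9, size=n_diff)
            sign = np.where(base[differing] < 0.5, 1.0, -1.0)
            mu[differing, k] = np.clip(base[differing] + sign * delta, 0.01, 0.99)
    return mu, differing


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _assign_genes(config: SimulationConfig, rng) -> pd.Series:
    """Probe -> gene symbol map; probes spread over genes roughly evenly."""
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    counts = rng.poisson(max(config.probes_per_gene_mean - 1, 0), size=config.n_genes) + 1
    owners = np.repeat(np.arange(config.n_genes), counts)
    if len(owners) < config.n_probes:
        owners = np.concatenate(
            [owners, rng.integers(0, config.n_genes, size=config.n_probes - len(owners))]
        )
    owners = rng.permutation(owners)[: config.n_probes]
    probe_ids = [f"cg{i:07d}" for i in range(1, config.n_probes + 1)]
    return pd.Series([genes[o] for o in owners], index=pd.Index(probe_ids, name="probe_id"))


def _make_annotation(config: SimulationConfig, gene_map: pd.Series, rng) -> tuple[pd.DataFrame, dict]:
    n = config.n_probes
    ann = pd.DataFrame(index=gene_map.index)
    ann["chr"] = rng.choice([str(c) for c in range(1, 23)] + ["X"], size=n)
    ann["pos"] = rng.integers(10_000, 200_000_000, size=n)
    ann["strand"] = rng.choice(["+", "-"], size=n)
    ann["gene"] = gene_map.values
    ann["design_type"] = np.where(rng.random(n) < config.frac_type2, "II", "I")
    ann["detection_p"] = np.round(rng.uniform(1e-5, 0.005, size=n), 6)
    ann["bead_count"] = rng.integers(5, 25, size=n)
    ann["has_cpg"] = True
    ann["snp_flag"] = False
    ann["multimap_flag"] = False

    # plant disjoint QC artifacts at the configured per-filter rates
    artifacts: dict[str, list[str]] = {}
    available = np.array(ann.index)
    rng.shuffle(available)
    cursor = 0
    for name in ARTIFACT_FILTERS:
        rate = float(config.qc_artifact_rates.get(name, 0.0))
        count = int(round(rate * n))
        ids = list(available[cursor : cursor + count])
        cursor += count
        artifacts[name] = ids
        if not ids:
            continue
        if name == "detection_p":
            ann.loc[ids, "detection_p"] = np.round(rng.uniform(0.011, 0.2, size=len(ids)), 6)
        elif name == "bead_count":
            ann.loc[ids, "bead_count"] = rng.integers(0, 3, size=len(ids))
        elif name == "no_cpg":
            ann.loc[ids, "has_cpg"] = False
        elif name == "snp_proximity":
            ann.loc[ids, "snp_flag"] = True
        elif name == "multi_mapping":
            ann.loc[ids, "multimap_flag"] = True
    return ann, artifacts


def _plant_effects(
    config: SimulationConfig,
    mu: np.ndarray,
    gene_map: pd.Series,
    effect_genes: list[str],
    group_mean_props: dict[str, np.ndarray],
    rng,
    differing_idx: list[int],
) -> pd.DataFrame:
    """Choose effect probes (concentrated on the effect genes) and target shifts.

    Returns a long table (probe_id, group, delta_beta) where delta_beta is
    the planted difference of generating mean betas between the effect group
    and the reference group.  Effect probes are drawn from probes whose
    baseline is shared across cell types: on cell-type-specific probes the
    group shift in mixing proportions would add its own mean difference and
    the planted delta would no longer equal the generating-mean difference.
    """
    probe_ids = gene_map.index.to_numpy()
    differing = set(differing_idx)
    ref_props = group_mean_props[config.reference_group]
    base_all = mu @ ref_props
    on_effect_genes = [
        i for i in np.where(gene_map.isin(effect_genes).to_numpy())[0] if i not in differing
    ]
    rows = []
    taken: set[int] = set()
    for eff in config.effects:
        pool = [i for i in on_effect_genes if i not in taken]
        if len(pool) < eff.n_probes:
            extra = [
                i
                for i in range(len(probe_ids))
                if i not in taken and i not in pool and i not in differing
            ]
            pool = pool + extra
        chosen = rng.choice(pool, size=eff.n_probes, replace=False)
        taken |= set(int(i) for i in chosen)
        mags = rng.uniform(eff.delta_beta[0], eff.delta_beta[1], size=eff.n_probes)
        signs = np.where(rng.random(eff.n_probes) < eff.frac_hyper, 1.0, -1.0)
        base = base_all[chosen]
        # keep the shifted mean inside (0.02, 0.98): flip the sign if needed
        signs = np.where(base + signs * mags > 0.98, -np.abs(signs), signs)
        signs = np.where(base + signs * mags < 0.02, np.abs(signs), signs)
        for i, m, s in zip(chosen, mags, signs):
            rows.append(
                {"probe_id": probe_ids[i], "group": eff.group, "delta_beta": float(s * m)}
            )
    return pd.DataFrame(rows, columns=["probe_id", "group", "delta_beta"])


def simulate_cohort(config: SimulationConfig) -> tuple[MethylationDataset, GroundTruth]:
    """Generate a beta matrix with latent mixing, planted effects and QC artifacts.

    Per sample j the probe mean is the mixture Mu @ omega_j; planted group
    effects shift the mean on the logit scale by the offset that moves the
    reference-group mean beta by exactly the planted delta, and the observed
    beta is drawn from a beta distribution with that mean and concentration
    ``noise_precision`` (``inf`` gives the noiseless limit).
    """
    root = np.random.default_rng(config.seed)
    seeds = root.spawn(5)
    mu, differing_idx = simulate_profiles(
        config.n_probes, config.k_true, seed=seeds[0], differing_fraction=config.differing_fraction
    )
    gene_map = _assign_genes(config, np.random.default_rng(seeds[1]))
    ann, artifacts = _make_annotation(config, gene_map, np.random.default_rng(seeds[2]))
    rng = np.random.default_rng(seeds[3])

    group_mean_props = {g.label: np.asarray(g.mean_props, float) for g in config.groups}
    # effect genes: genes carrying the planted probes (module overlap target)
    all_genes = sorted(gene_map.unique())
    eff_rng = np.random.default_rng(seeds[4])
    effect_genes = sorted(
        eff_rng.choice(all_genes, size=min(config.n_effect_genes, len(all_genes)), replace=False)
    )
    effects = _plant_effects(
        config, mu, gene_map, effect_genes, group_mean_props, eff_rng, differing_idx
    )

    sample_rows = []
    omega_rows = []
    betas = {}
    probe_index = gene_map.index
    pos = {p: i for i, p in enumerate(probe_index)}
    for g in config.groups:
        props = group_mean_props[g.label]
        planted = effects[effects["group"] == g.label]
        offsets = np.zeros(config.n_probes)
        if not planted.empty:
            idx = np.array([pos[p] for p in planted["probe_id"]])
            ref_mean = mu[idx] @ group_mean_props[config.reference_group]
            target = np.clip(ref_mean + planted["delta_beta"].to_numpy(), 0.01, 0.99)
            offsets[idx] = _logit(target) - _logit(ref_mean)
        for j in range(g.n_samples):
            sid = f"{g.label}_{j + 1:02d}"
            if config.omega_concentration == np.inf:
                w = props.copy()
            else:
                w = rng.dirichlet(np.maximum(props * config.omega_concentration, 1e-3))
            mean = np.clip(mu @ w, 0.005, 0.995)
            if offsets.any():
                mean = _expit(_logit(mean) + offsets)
            if np.isinf(config.noise_precision):
                beta = mean
            else:
                nu = config.noise_precision
                beta = rng.beta(np.maximum(mean * nu, 1e-3), np.maximum((1 - mean) * nu, 1e-3))
            betas[sid] = np.clip(beta, 1e-4, 1 - 1e-4)
            sample_rows.append({"sample_id": sid, "group": g.label, "memory_fraction": w[-1]})
            omega_rows.append(w)

    beta_df = pd.DataFrame(betas, index=probe_index)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    omega = pd.DataFrame(
        omega_rows, index=samples.index, columns=[f"celltype_{k}" for k in range(config.k_true)]
    )
    dataset = MethylationDataset(betas=beta_df, samples=samples, annotation=ann)
    truth = GroundTruth(
        omega=omega,
        mu=pd.DataFrame(mu, index=probe_index, columns=omega.columns),
        effects=effects,
        differing_probes=[probe_index[i] for i in differing_idx],
        artifact_probes=artifacts,
        probe_gene_map=gene_map,
        effect_genes=effect_genes,
        reference_group=config.reference_group,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------


def preferential_attachment_edges(n: int, m: int, rng) -> list[tuple[int, int]]:
    """Scale-free graph grown from an (m+1)-clique seed.

    Every later node attaches m edges preferentially; the edge count is
    therefore m*(n-m-1) + m*(m+1)/2.
    """
    if n <= m + 1:
        raise ValueError("need n > m+1 nodes")
    edges = [(i, j) for i in range(m + 1) for j in range(i + 1, m + 1)]
    attachment: list[int] = [v for e in edges for v in e]
    for new in range(m + 1, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(int(attachment[rng.integers(0, len(attachment))]))
        for t in targets:
            edges.append((t, new))
            attachment.extend((t, new))
    return edges


def simulate_network(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[PPINetwork, GroundTruth]:
    """Scale-free PPI background with a planted dense module.

    The planted module (a clique by default) is placed preferentially on the
    cohort's effect genes so the module detectors have a recoverable target;
    all emitted scores are at or above the configured threshold.
    """
    spec = config.network
    if spec.module_size < 3:
        raise ValueError("planted module size must be >= 3")
    if spec.module_size >= spec.n_nodes:
        raise ValueError("planted module must be smaller than the network")
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 7)

    effect_genes = list(truth.effect_genes) if truth is not None else []
    fillers = [f"N{i:04d}" for i in range(1, spec.n_nodes + 1)]
    names = (effect_genes + [f for f in fillers])[: spec.n_nodes]
    if truth is not None and truth.probe_gene_map is not None:
        other = [g for g in sorted(truth.probe_gene_map.unique()) if g not in effect_genes]
        names = (effect_genes + other + fillers)[: spec.n_nodes]

    raw = preferential_attachment_edges(spec.n_nodes, spec.m, rng)
    perm = rng.permutation(spec.n_nodes)  # decouple attachment order from gene identity
    name_of = {i: names[perm[i]] for i in range(spec.n_nodes)}
    scores = rng.integers(spec.score_threshold, 961, size=len(raw))
    edges = [(name_of[u], name_of[v], int(s)) for (u, v), s in zip(raw, scores)]

    module_pool = [g for g in effect_genes if g in set(names)] or names
    module_genes = sorted(
        rng.choice(module_pool, size=min(spec.module_size, len(module_pool)), replace=False)
    )
    if len(module_genes) < spec.module_size:
        extra = [g for g in names if g not in module_genes]
        module_genes += extra[: spec.module_size - len(module_genes)]
    if spec.planted_clique:
        for i, u in enumerate(module_genes):
            for v in module_genes[i + 1 :]:
                edges.append((u, v, spec.module_score))

    network = build_network(edges, min_score=spec.score_threshold)
    out_truth = GroundTruth(
        module_genes=sorted(module_genes),
        effect_genes=effect_genes,
        probe_gene_map=truth.probe_gene_map if truth is not None else None,
    )
    return network, out_truth


# ---------------------------------------------------------------------------
# disease cohorts
# ---------------------------------------------------------------------------


def simulate_disease_cohort(
    config: SimulationConfig,
    pregnancy_truth: GroundTruth,
    effect_group: str = "T2",
    disease: DiseaseSpec | None = None,
    seed_offset: int = 1,
) -> tuple[MethylationDataset, GroundTruth]:
    """Case/control cohort whose effects sit on the pregnancy effect probes.

    Case generating-mean differences equal ``effect_sign * effect_scale``
    times the pregnancy differences on the shared probes, so the generating
    effect vectors are exactly (anti)proportional.  A floor(overlap_fraction
    * n_controls) subset of controls receives case-like profiles and is
    listed in the returned ground truth.
    """
    spec = disease or config.disease
    if not 0 <= spec.overlap_fraction < 1:
        raise ValueError("overlap fraction must lie in [0, 1)")
    preg_effects = pregnancy_truth.effect_table(effect_group)
    if preg_effects.empty:
        raise ValueError(f"pregnancy truth has no effects for group {effect_group}")
    mu = pregnancy_truth.mu.to_numpy()
    probe_index = pregnancy_truth.mu.index
    k = mu.shape[1]

    shared = preg_effects.index.to_list()
    if spec.n_shared_probes is not None:
        shared = shared[: spec.n_shared_probes]
    disease_delta = spec.effect_sign * spec.effect_scale * preg_effects.loc[shared]

    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + seed_offset)
    props = np.full(k, 1.0 / k)
    pos = {p: i for i, p in enumerate(probe_index)}
    idx = np.array([pos[p] for p in shared])
    base_mean = mu[idx] @ props
    target = np.clip(base_mean + disease_delta.to_numpy(), 0.01, 0.99)
    offsets = np.zeros(len(probe_index))
    offsets[idx] = _logit(target) - _logit(base_mean)
    realized = pd.Series(target - base_mean, index=shared)

    n_overlap = int(math.floor(spec.overlap_fraction * spec.n_controls))
    overlap_ids = [f"{spec.control_label}_{j + 1:02d}" for j in range(n_overlap)]

    betas = {}
    sample_rows = []
    omega_rows = []
    for label, count in ((spec.control_label, spec.n_controls), (spec.case_label, spec.n_cases)):
        for j in range(count):
            sid = f"{label}_{j + 1:02d}"
            case_like = label == spec.case_label or sid in overlap_ids
            w = rng.dirichlet(np.maximum(props * config.omega_concentration, 1e-3))
            mean = np.clip(mu @ w, 0.005, 0.995)
            if case_like:
                mean = _expit(_logit(mean) + offsets)
            if np.isinf(config.noise_precision):
                beta = mean
            else:
                nu = config.noise_precision
                beta = rng.beta(np.maximum(mean * nu, 1e-3), np.maximum((1 - mean) * nu, 1e-3))
            betas[sid] = np.clip(beta, 1e-4, 1 - 1e-4)
            sample_rows.append({"sample_id": sid, "group": label})
            omega_rows.append(w)

    beta_df = pd.DataFrame(betas, index=probe_index)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    ann = _clean_annotation(pregnancy_truth, probe_index)
    dataset = MethylationDataset(betas=beta_df, samples=samples, annotation=ann)
    effects = pd.DataFrame(
        {
            "probe_id": shared,
            "group": spec.case_label,
            "delta_beta": realized.to_numpy(),
        }
    )
    truth = GroundTruth(
        omega=pd.DataFrame(
            omega_rows, index=samples.index, columns=[f"celltype_{i}" for i in range(k)]
        ),
        mu=pregnancy_truth.mu,
        effects=effects,
        probe_gene_map=pregnancy_truth.probe_gene_map,
        effect_genes=pregnancy_truth.effect_genes,
        overlap_controls=overlap_ids,
        reference_group=spec.control_label,
    )
    return dataset, truth


def _clean_annotation(truth: GroundTruth, probe_index) -> pd.DataFrame:
    """Artifact-free annotation sharing the pregnancy cohort's probe->gene map."""
    n = len(probe_index)
    ann = pd.DataFrame(index=probe_index)
    ann["chr"] = "1"
    ann["pos"] = np.arange(1, n + 1) * 1000
    ann["strand"] = "+"
    gm = truth.probe_gene_map
    ann["gene"] = gm.loc[probe_index].values if gm is not None else "NA"
    ann["design_type"] = "II"
    ann["detection_p"] = 0.001
    ann["bead_count"] = 10
    ann["has_cpg"] = True
    ann["snp_flag"] = False
    ann["multimap_flag"] = False
    return ann


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_cohort(dataset: MethylationDataset, truth: GroundTruth, outdir) -> None:
    """TSV/CSV/JSON export of a simulated cohort and its ground truth."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.betas.to_csv(outdir / "betas.tsv", sep="\t")
    dataset.samples.to_csv(outdir / "samples.csv")
    dataset.annotation.to_csv(outdir / "annotation.tsv", sep="\t")
    if truth.omega is not None:
        truth.omega.to_csv(outdir / "truth_omega.tsv", sep="\t")
    if truth.effects is not None:
        truth.effects.to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")


def write_network(network: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v, s in sorted(network.graph.edges(data="score")):
            fh.write(f"{u}\t{v}\t{int(s)}\n")


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = parts[2:]
    return out
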