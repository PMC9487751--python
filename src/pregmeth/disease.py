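"""Disease relevance: subgroup selection, enrichment and directionality.

Heterogeneous case/control methylation cohorts often contain a subgroup of
controls whose profiles overlap the cases, masking the large-scale group
difference.  The divisive subgroup selection here greedily excludes the
samples (controls only by default) whose removal most increases the DMP
count between the retained groups — an extreme-group strategy that recovers
the separable core of the cohort.  The retained groups' DMPs are then tested
for enrichment against known disease gene sets and against the pregnancy
module CpGs (Fisher's exact test with fold enrichment), and the signed
pregnancy and disease effects on the overlapping CpGs are correlated
(Pearson and Spearman) to call the directionality of the relationship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import adjust_fdr, build_design, compute_delta_beta, fit_probe_models
from .preprocess import MethylationDataset, beta_to_m

log = logging.getLogger(__name__)


@dataclass
class DMCriterion:
    """Joint FDR / effect-size rule defining a DMP."""

    q_thresh: float = 0.05
    db_thresh: float = 0.05


@dataclass
class SubgroupSelection:
    retained_cases: list[str]
    retained_controls: list[str]
    removed: list[tuple[str, float]]  # (sample id, score after its removal)
    score_trace: list[float]
    final_score: int  # DMP count between the retained groups

    @property
    def removed_ids(self) -> list[str]:
        return [s for s, _ in self.removed]


def _separation_score(
    dataset: MethylationDataset,
    case_ids: list[str],
    control_ids: list[str],
    criterion: DMCriterion,
    moderated: bool = True,
    score: str = "neglogq",
    omega: pd.DataFrame | None = None,
) -> tuple[float, int]:
    """(score, DMP count) between the retained groups.

    ``score='dmp_count'`` is the plain count of probes passing the joint
    criterion.  ``score='neglogq'`` (default) sums -log10 q over those
    probes: removing an overlapping control strengthens every true DMP
    multiplicatively, while removing a clean sample costs degrees of freedom
    and weakens the score, which makes the greedy search far less prone to
    chance-driven removals than the bare count.
    """
    ids = list(control_ids) + list(case_ids)
    sub = dataset.subset_samples(ids)
    groups = pd.Series(
        ["control"] * len(control_ids) + ["case"] * len(case_ids), index=ids, name="group"
    )
    samples = pd.DataFrame({"group": groups})
    design = build_design(samples, omega, reference_group="control")
    m = beta_to_m(sub.betas)
    fit = fit_probe_models(m, design, contrasts={"case_vs_control": ("case", None)}, moderated=moderated)
    table = fit.xs("case_vs_control", level="contrast")
    q = adjust_fdr(table["p"].to_numpy())
    db = compute_delta_beta(sub.betas, groups, ("control", "case"))
    db = db.loc[table.index].to_numpy()
    is_dmp = (q < criterion.q_thresh) & (np.abs(db) > criterion.db_thresh)
    count = int(is_dmp.sum())
    if score == "dmp_count":
        return float(count), count
    return float(np.minimum(-np.log10(np.maximum(q[is_dmp], 1e-30)), 30).sum()), count


def vista_subgroups(
    dataset: MethylationDataset,
    case_label: str = "case",
    control_label: str = "control",
    dm_criterion: DMCriterion | None = None,
    max_removed_fraction: float = 0.5,
    removable: str = "controls",
    min_group: int = 3,
    seed: int = 0,
    moderated: bool = True,
    min_improvement_frac: float = 0.10,
    score: str = "neglogq",
    adjust_k: int | None = 2,
) -> SubgroupSelection:
    """Greedy divisive subgroup selection maximizing the DMP count.

    Each step evaluates removing every currently removable sample and
    accepts the single removal that most increases the DMP count between the
    retained groups; stops when no removal improves the score by more than
    ``min_improvement_frac`` of the current score (greedily maximizing over
    candidates inflates small chance improvements, so a margin is required),
    when the removable pool would shrink below ``min_group``, or when
    ``max_removed_fraction`` of the removable class is gone.  Deterministic
    given the inputs; ties break by sample id.

    The separation score is adjusted for cell composition: the cohort is
    deconvolved once up front into ``adjust_k`` latent cell types and the
    proportion columns enter every candidate fit, mirroring the main chain
    (``adjust_k=None`` disables the adjustment).  Without it, chance
    composition imbalance between the groups can dominate the DMP count and
    misdirect the search.
    """
    criterion = dm_criterion or DMCriterion()
    groups = dataset.groups().astype(str)
    cases = sorted(groups.index[groups == case_label])
    controls = sorted(groups.index[groups == control_label])
    if len(cases) < 3 or len(controls) < 3:
        raise ValueError("need at least 3 samples per label")
    if removable not in ("controls", "either"):
        raise ValueError("removable must be 'controls' or 'either'")

    omega = None
    if adjust_k is not None and adjust_k > 1:
        from .deconv import reffree_decompose

        omega = reffree_decompose(dataset.betas, adjust_k, seed=seed, n_restarts=3).omega
    retained_cases = list(cases)
    retained_controls = list(controls)
    cur, n_dmps = _separation_score(
        dataset, retained_cases, retained_controls, criterion, moderated, score, omega
    )
    trace = [cur]
    removed: list[tuple[str, float]] = []
    n_removable0 = len(controls) + (len(cases) if removable == "either" else 0)
    max_removed = int(np.floor(max_removed_fraction * n_removable0))

    while len(removed) < max_removed:
        candidates = []
        if len(retained_controls) > min_group:
            candidates += [("control", s) for s in retained_controls]
        if removable == "either" and len(retained_cases) > min_group:
            candidates += [("case", s) for s in retained_cases]
        best = None
        for kind, sid in sorted(candidates, key=lambda t: t[1]):
            cs = [s for s in retained_cases if s != sid]
            ct = [s for s in retained_controls if s != sid]
            cand, cand_dmps = _separation_score(
                dataset, cs, ct, criterion, moderated, score, omega
            )
            if best is None or cand > best[0]:
                best = (cand, cand_dmps, kind, sid)
        if best is None or best[0] <= cur + max(1.0, min_improvement_frac * cur):
            break
        cur, n_dmps, kind, sid = best
        if kind == "control":
            retained_controls.remove(sid)
        else:
            retained_cases.remove(sid)
        removed.append((sid, cur))
        trace.append(cur)
        log.info("removed %s (%s); separation score now %.1f (%d DMPs)", sid, kind, cur, n_dmps)

    return SubgroupSelection(
        retained_cases=retained_cases,
        retained_controls=retained_controls,
        removed=removed,
        score_trace=trace,
        final_score=n_dmps,
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    a: int  # query & target
    b: int  # query only
    c: int  # target only
    d: int  # neither
    fold_enrichment: float
    p: float
    background: int
    overlap_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "N": self.background,
            "fold_enrichment": self.fold_enrichment,
            "p": self.p,
        }


def fisher_table(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(fold enrichment, two-sided Fisher p) of the 2x2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    if a + b == 0 or a + c == 0:
        raise ValueError("query and target must be non-empty")
    fe = (a / (a + b)) / ((a + c) / n)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return fe, p


def fisher_margin_scan(r: int, c: int, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided Fisher p and FE for every feasible table with fixed margins.

    For row-1 total ``r`` (query size), column-1 total ``c`` (target size)
    and universe ``n``, returns (support, fold enrichment, p) over all
    feasible overlaps a.  Vectorized over the hypergeometric support, so
    scanning many tables (e.g. every clique of a network) costs one pmf
    evaluation per margin set instead of one test per table.
    """
    if r < 1 or c < 1 or n < max(r, c):
        raise ValueError("need 1 <= r, c <= n")
    lo = max(0, r + c - n)
    hi = min(r, c)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c, r)
    # two-sided: total mass of tables no more likely than the observed one
    rel = pmf[None, :] <= pmf[:, None] * (1 + 1e-9)
    p = np.clip((pmf[None, :] * rel).sum(axis=1), 0.0, 1.0)
    fe = (support / r) / (c / n)
    return support, fe, p


def geneset_enrichment(query_genes, target_genes, background_genes) -> EnrichmentResult:
    """Fisher's exact enrichment of ``target`` among ``query`` on ``background``.

    Both sets must be subsets of the background universe; fold enrichment is
    (overlap / query size) / (target size / background size).  The choice of
    background matters for FE, so the universe size is carried in the result.
    """
    background = set(background_genes)
    if len(background) < 4:
        raise ValueError("background must contain at least 4 elements")
    query = set(query_genes) & background
    target = set(target_genes) & background
    if not query or not target:
        raise ValueError("empty query or target set")
    overlap = query & target
    a = len(overlap)
    b = len(query) - a
    c = len(target) - a
    d = len(background) - a - b - c
    fe, p = fisher_table(a, b, c, d)
    return EnrichmentResult(
        a=a, b=b, c=c, d=d, fold_enrichment=fe, p=p,
        background=len(background), overlap_ids=sorted(overlap),
    )


def cpg_enrichment(module_cpgs, disease_dmps, background_cpgs) -> EnrichmentResult:
    """Enrichment of disease DMPs among the module CpGs, on the CpG universe.

    The returned overlap ids feed the directionality correlation.  A fully
    disjoint pair yields FE = 0 with the exact Fisher tail as p.
    """
    background = set(background_cpgs)
    module = set(module_cpgs) & background
    disease = set(disease_dmps) & background
    if not module or not disease:
        raise ValueError("empty module or disease CpG set")
    a = len(module & disease)
    b = len(module) - a
    c = len(disease) - a
    d = len(background) - a - b - c
    fe, p = fisher_table(a, b, c, d)
    return EnrichmentResult(
        a=a, b=b, c=c, d=d, fold_enrichment=fe, p=p,
        background=len(background), overlap_ids=sorted(module & disease),
    )


# ---------------------------------------------------------------------------
# directionality
# ---------------------------------------------------------------------------


@dataclass
class DirectionalityResult:
    overlap_ids: list[str]
    pregnancy_effects: np.ndarray
    disease_effects: np.ndarray
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float

    @property
    def sign(self) -> int:
        return int(np.sign(self.pearson_r))

    def to_dict(self) -> dict:
        return {
            "n_overlap": len(self.overlap_ids),
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "sign": self.sign,
        }


def direction_correlation(
    module_effects: pd.Series,
    disease_effects: pd.Series,
    overlap_ids=None,
) -> DirectionalityResult:
    """Pearson and Spearman correlation of paired pregnancy/disease effects.

    Effects are signed per-CpG differences (delta beta or M difference) and
    are paired on ``overlap_ids`` (default: the index intersection).  At
    least 3 overlapping CpGs with non-degenerate variance are required.
    """
    if overlap_ids is None:
        overlap_ids = module_effects.index.intersection(disease_effects.index)
    overlap_ids = list(overlap_ids)
    if len(overlap_ids) < 3:
        raise ValueError("need at least 3 overlapping CpGs")
    x = module_effects.loc[overlap_ids].to_numpy(float)
    y = disease_effects.loc[overlap_ids].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance effect vector")
    r, rp = stats.pearsonr(x, y)
    rho, sp = stats.spearmanr(x, y)
    return DirectionalityResult(
        overlap_ids=overlap_ids,
        pregnancy_effects=x,
        disease_effects=y,
        pearson_r=float(r),
        pearson_p=float(rp),
        spearman_rho=float(rho),
        spearman_p=float(sp),
    )
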