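"""Probe-level QC filtering, BMIQ-style normalization and beta/M transforms.

Betas are methylation fractions in [0, 1], typically bimodal across probes.
Linear modelling happens on M-values, M = log2(beta / (1 - beta)), which
stabilizes the variance near the boundaries.  Type II Infinium probes have a
compressed dynamic range relative to type I probes; the BMIQ-style step fits a
three-state beta mixture (unmethylated / hemimethylated / methylated) to each
design type per sample and quantile-matches the type II states onto the type I
reference.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: clipping constant for the logit transform
DEFAULT_EPS = 1e-3

#: fixed order of the five QC filters; the per-filter removal counts are
#: computed sequentially, so the order is part of the contract.
FILTER_ORDER = (
    "detection_p",
    "bead_count",
    "no_cpg",
    "snp_proximity",
    "multi_mapping",
)

REQUIRED_ANNOTATION = {
    "detection_p": "detection_p",
    "bead_count": "bead_count",
    "no_cpg": "has_cpg",
    "snp_proximity": "snp_flag",
    "multi_mapping": "multimap_flag",
}


class AnnotationError(KeyError):
    """A required probe-annotation column is missing."""


@dataclass
class MethylationDataset:
    """Beta matrix (probes x samples) plus sample sheet and probe annotation.

    ``betas`` is indexed by probe id with sample-id columns; ``samples`` is
    indexed by sample id and carries at least a ``group`` column;
    ``annotation`` is indexed by probe id.
    """

    betas: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.betas.index.equals(self.annotation.index):
            self.annotation = self.annotation.loc[self.betas.index]
        if list(self.betas.columns) != list(self.samples.index):
            self.samples = self.samples.loc[self.betas.columns]

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def groups(self) -> pd.Series:
        return self.samples["group"]

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        return MethylationDataset(
            self.betas.loc[probe_ids],
            self.samples.copy(),
            self.annotation.loc[probe_ids],
        )

    def subset_samples(self, sample_ids) -> "MethylationDataset":
        return MethylationDataset(
            self.betas[list(sample_ids)],
            self.samples.loc[list(sample_ids)],
            self.annotation.copy(),
        )


@dataclass
class FilterReport:
    """Sequential removal bookkeeping for the five-probe-QC rules."""

    input_probes: int
    removed: dict[str, list[str]] = field(default_factory=dict)
    retained: int = 0
    filter_order: tuple[str, ...] = FILTER_ORDER

    @property
    def removed_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.removed.items()}

    def check_conservation(self) -> bool:
        return self.retained + sum(self.removed_counts.values()) == self.input_probes

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"filter": name, "removed": len(self.removed.get(name, []))}
            for name in self.filter_order
        ]
        rows.append({"filter": "retained", "removed": self.retained})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "input_probes": self.input_probes,
            "removed_counts": self.removed_counts,
            "retained": self.retained,
            "filter_order": list(self.filter_order),
        }


@dataclass
class FilterThresholds:
    """Thresholds of the five QC rules.

    A probe fails the detection-p rule when its detection p exceeds
    ``detection_p`` in at least ``detection_fraction`` of samples (the
    annotation carries the per-probe worst-case detection p, so the default
    fraction of 0 means "in at least one sample").  Bead-count failures are
    strict: only counts strictly below ``min_beads`` fail.
    """

    detection_p: float = 0.01
    detection_fraction: float = 0.0
    min_beads: int = 3
    drop_x: bool = False


def filter_probes(
    dataset: MethylationDataset,
    thresholds: FilterThresholds | None = None,
) -> tuple[MethylationDataset, FilterReport]:
    """Apply the five probe-QC rules sequentially and report removals.

    Rules, in fixed order: (1) detection p above threshold, (2) bead count
    below ``min_beads``, (3) probe without an actual CpG at the interrogated
    position, (4) probe near a SNP, (5) probe aligning to multiple loci.
    Each rule's removals are counted among probes surviving the earlier rules,
    so the counts are disjoint and sum with the retained count to the input
    probe count.  X-chromosome probes are retained by default (all-female
    designs).
    """
    thresholds = thresholds or FilterThresholds()
    ann = dataset.annotation
    for rule, col in REQUIRED_ANNOTATION.items():
        if col not in ann.columns:
            raise AnnotationError(
                f"probe annotation lacks column {col!r} required by filter {rule!r}"
            )

    report = FilterReport(input_probes=dataset.n_probes)
    surviving = ann.index.to_numpy()

    def _apply(name: str, fail_mask: pd.Series) -> None:
        nonlocal surviving
        failed = fail_mask.loc[surviving]
        removed_ids = failed.index[failed.to_numpy(bool)]
        report.removed[name] = list(removed_ids)
        surviving = failed.index[~failed.to_numpy(bool)].to_numpy()

    _apply("detection_p", ann["detection_p"] > thresholds.detection_p)
    _apply("bead_count", ann["bead_count"] < thresholds.min_beads)
    _apply("no_cpg", ~ann["has_cpg"].astype(bool))
    _apply("snp_proximity", ann["snp_flag"].astype(bool))
    _apply("multi_mapping", ann["multimap_flag"].astype(bool))
    if thresholds.drop_x and "chr" in ann.columns:
        _apply("x_chromosome", ann["chr"].astype(str).isin({"X", "chrX"}))
        report.filter_order = FILTER_ORDER + ("x_chromosome",)

    report.retained = len(surviving)
    filtered = dataset.subset_probes(surviving)
    log.info(
        "probe filtering retained %d of %d probes (%s)",
        report.retained,
        report.input_probes,
        report.removed_counts,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# beta <-> M transforms
# ---------------------------------------------------------------------------


def beta_to_m(beta, eps: float = DEFAULT_EPS):
    """M = log2(beta / (1 - beta)) after clipping beta to [eps, 1 - eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (1 + 2^M); exact inverse on [eps, 1-eps]."""
    x = np.asarray(m, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-x[pos]))
    out[~pos] = np.exp2(x[~pos]) / (1.0 + np.exp2(x[~pos]))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index)
    return out


# ---------------------------------------------------------------------------
# BMIQ-style normalization
# ---------------------------------------------------------------------------


def _beta_mm(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted method-of-moments estimate of beta-distribution (a, b)."""
    wsum = w.sum()
    if wsum <= 0:
        return 1.0, 1.0
    mu = float(np.dot(w, x) / wsum)
    var = float(np.dot(w, (x - mu) ** 2) / wsum)
    mu = min(max(mu, 1e-4), 1 - 1e-4)
    var = max(var, 1e-6)
    common = max(mu * (1 - mu) / var - 1.0, 0.1)
    return max(mu * common, 0.05), max((1 - mu) * common, 0.05)


@dataclass
class BetaMixtureFit:
    """Three-state beta mixture (unmethylated / hemi / methylated)."""

    params: list[tuple[float, float]]
    weights: np.ndarray
    converged: bool
    n_iter: int

    def classify(self, x: np.ndarray) -> np.ndarray:
        dens = np.stack(
            [w * stats.beta.pdf(x, a, b) for (a, b), w in zip(self.params, self.weights)]
        )
        return np.argmax(dens, axis=0)

    def state_mean(self, state: int) -> float:
        a, b = self.params[state]
        return a / (a + b)


def fit_beta_mixture(
    x: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> BetaMixtureFit:
    """EM fit of a 3-state beta mixture, initialized at the canonical states.

    On non-convergence within ``max_iter`` a warning is emitted and the last
    iterate is returned (downstream falls back to an identity map for states
    whose fit is degenerate).
    """
    x = np.clip(np.asarray(x, float), 1e-4, 1 - 1e-4)
    # data-driven initialization: hard-assign states at 0.25 / 0.75 and take
    # per-state moments, so fits of two samples from one distribution start
    # (and end) in consistent configurations
    init_state = np.digitize(x, [0.25, 0.75])
    params = []
    weights = np.empty(3)
    for k in range(3):
        w = (init_state == k).astype(float)
        weights[k] = max(w.mean(), 1e-3)
        params.append(_beta_mm(x, w) if w.sum() >= 5 else [(2.0, 10.0), (5.0, 5.0), (10.0, 2.0)][k])
    weights = weights / weights.sum()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = np.stack(
            [w * stats.beta.pdf(x, a, b) for (a, b), w in zip(params, weights)]
        )
        tot = dens.sum(axis=0)
        tot[tot <= 0] = np.finfo(float).tiny
        resp = dens / tot
        new_weights = resp.mean(axis=1)
        new_params = [_beta_mm(x, resp[k]) for k in range(3)]
        # keep each state's mean in its canonical band so the three
        # components cannot drift into each other's roles (mode swapping
        # would make fits of comparable samples inconsistent)
        bands = ((0.005, 0.30), (0.30, 0.70), (0.70, 0.995))
        projected = []
        for (a, b), (lo, hi) in zip(new_params, bands):
            mean = a / (a + b)
            conc = a + b
            mean = min(max(mean, lo), hi)
            projected.append((max(mean * conc, 0.05), max((1 - mean) * conc, 0.05)))
        new_params = projected
        # the moment-based M-step is not likelihood-monotone, so convergence
        # is judged on the state means and weights rather than the ll
        delta = max(
            float(np.max(np.abs(new_weights - weights))),
            max(
                abs(a / (a + b) - a0 / (a0 + b0))
                for (a, b), (a0, b0) in zip(new_params, params)
            ),
        )
        weights, params = new_weights, new_params
        if delta < max(tol, 1e-7) * 100:
            converged = True
            break
    if not converged:
        warnings.warn("beta-mixture EM did not converge; using last iterate")
        log.warning("beta-mixture EM non-convergence after %d iterations", it)
    # order states by their means so state 0/1/2 = unmeth/hemi/meth
    order = np.argsort([a / (a + b) for a, b in params])
    params = [params[i] for i in order]
    weights = weights[order]
    return BetaMixtureFit(params=params, weights=weights, converged=converged, n_iter=it)


def _refit_states(x: np.ndarray, pooled: BetaMixtureFit) -> BetaMixtureFit:
    """Per-design-type mixture: pooled-fit responsibilities, type-specific moments.

    Sharing the state responsibilities of a pooled fit keeps the two design
    types' fits in the same configuration (the per-type EMs can otherwise
    settle in different local modes on middle-heavy samples), while the
    type-specific weighted moments still capture the actual distributional
    difference the map must correct.
    """
    x = np.clip(np.asarray(x, float), 1e-4, 1 - 1e-4)
    dens = np.stack(
        [w * stats.beta.pdf(x, a, b) for (a, b), w in zip(pooled.params, pooled.weights)]
    )
    tot = dens.sum(axis=0)
    tot[tot <= 0] = np.finfo(float).tiny
    resp = dens / tot
    params = [_beta_mm(x, resp[k]) for k in range(3)]
    return BetaMixtureFit(
        params=params,
        weights=resp.mean(axis=1),
        converged=pooled.converged,
        n_iter=pooled.n_iter,
    )


def fit_design_type_mixtures(
    x1: np.ndarray,
    x2: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[BetaMixtureFit, BetaMixtureFit]:
    """Consistent 3-state fits for the type I and type II betas of one sample."""
    pooled = fit_beta_mixture(np.concatenate([x1, x2]), tol=tol, max_iter=max_iter)
    return _refit_states(x1, pooled), _refit_states(x2, pooled)


def _bmiq_map_sample(x2: np.ndarray, fit1: BetaMixtureFit, fit2: BetaMixtureFit) -> np.ndarray:
    """Monotone map of one sample's type II betas onto the type I scale.

    U and M states are quantile-matched through the fitted beta CDFs; the
    intermediate state is linearly dilated into the gap between the mapped
    state boundaries.  Monotonicity is enforced by building the map on a fine
    grid and taking the running maximum before interpolation.
    """
    grid = np.linspace(0.0, 1.0, 2001)
    states = fit2.classify(np.clip(grid, 1e-4, 1 - 1e-4))
    mapped = grid.copy()

    aU2, bU2 = fit2.params[0]
    aU1, bU1 = fit1.params[0]
    aM2, bM2 = fit2.params[2]
    aM1, bM1 = fit1.params[2]

    u_mask = states == 0
    m_mask = states == 2
    h_mask = states == 1
    q = stats.beta.cdf(grid[u_mask], aU2, bU2)
    mapped[u_mask] = stats.beta.ppf(np.clip(q, 1e-12, 1 - 1e-12), aU1, bU1)
    q = stats.beta.cdf(grid[m_mask], aM2, bM2)
    mapped[m_mask] = stats.beta.ppf(np.clip(q, 1e-12, 1 - 1e-12), aM1, bM1)

    if h_mask.any():
        lo_in, hi_in = grid[h_mask].min(), grid[h_mask].max()
        lo_out = mapped[u_mask].max() if u_mask.any() else lo_in
        hi_out = mapped[m_mask].min() if m_mask.any() else hi_in
        if hi_in > lo_in and hi_out > lo_out:
            mapped[h_mask] = lo_out + (grid[h_mask] - lo_in) * (hi_out - lo_out) / (
                hi_in - lo_in
            )
        # else: identity for the hemi state (degenerate fit)
    mapped = np.maximum.accumulate(np.clip(mapped, 0.0, 1.0))
    return np.interp(x2, grid, mapped)


def bmiq_normalize(
    dataset: MethylationDataset,
    min_probes_per_type: int = 100,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MethylationDataset:
    """Normalize type II probes to the type I reference distribution.

    Per sample: fit 3-state beta mixtures to the type I and type II betas,
    quantile-match the type II unmethylated and methylated states onto the
    type I fits and dilate the intermediate state into the remaining gap.
    Type I probes pass through unchanged; output stays in [0, 1] and the
    per-sample rank order within type II probes is preserved.
    """
    ann = dataset.annotation
    if "design_type" not in ann.columns:
        raise AnnotationError("probe annotation lacks column 'design_type'")
    is2 = ann["design_type"].astype(str).str.upper().isin({"II", "2"})
    if not is2.any():
        return dataset
    if is2.sum() < min_probes_per_type or (~is2).sum() < min_probes_per_type:
        raise ValueError(
            f"BMIQ needs at least {min_probes_per_type} probes of each design type"
        )
    out = dataset.betas.copy()
    x1_all = dataset.betas.loc[~is2]
    x2_all = dataset.betas.loc[is2]
    for sample in dataset.betas.columns:
        fit1, fit2 = fit_design_type_mixtures(
            x1_all[sample].to_numpy(), x2_all[sample].to_numpy(), tol=tol, max_iter=max_iter
        )
        out.loc[is2, sample] = _bmiq_map_sample(
            x2_all[sample].to_numpy(), fit1, fit2
        )
    return dataclasses.replace(dataset, betas=out)
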