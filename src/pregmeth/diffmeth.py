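"""Per-probe linear modelling on M-values with cell-composition adjustment.

The model per probe is  M = X b0 + Omega b1 + e,  where X carries the group
indicators (reference group absorbed into the intercept) and Omega the
deconvolved cell-type proportions (K-1 columns, since simplex rows plus an
intercept are collinear).  Residual variances are shrunk by empirical-Bayes
moderation (posterior s2 = (d0*s02 + d*s2) / (d0 + d), with the prior d0 and
s02 estimated by method of moments on log s2), giving moderated t statistics
on d0 + d degrees of freedom.  A probe is a DMP when its BH-adjusted q is
below ``q_thresh`` and its raw group-mean beta difference exceeds
``db_thresh`` in magnitude; genes with at least one DMP become DMGs with a
majority-rule direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

CONTRAST_NAMES = ("T1_vs_NP", "T2_vs_NP", "T2_vs_T1")


class DesignError(ValueError):
    """Rank-deficient or misaligned design matrix."""


@dataclass
class DesignMatrix:
    """Fixed effects (intercept + group dummies) plus omega adjustment columns."""

    matrix: pd.DataFrame  # samples x columns
    groups: pd.Series
    reference_group: str
    group_columns: list[str]

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)


def build_design(
    samples: pd.DataFrame,
    omega: pd.DataFrame | None = None,
    reference_group: str | None = None,
    drop_omega_column: int | None = -1,
) -> DesignMatrix:
    """Intercept + group indicators + K-1 omega columns.

    One omega column (the last by default) is dropped because the simplex
    rows together with the intercept would be collinear.  Raises
    :class:`DesignError` naming the offending columns if the result is still
    rank deficient.
    """
    groups = samples["group"].astype(str)
    levels = list(dict.fromkeys(groups))
    if reference_group is None:
        reference_group = levels[0]
    if reference_group not in levels:
        raise DesignError(f"reference group {reference_group!r} not among {levels}")
    cols = {"intercept": np.ones(len(groups))}
    group_cols = []
    for lv in levels:
        if lv == reference_group:
            continue
        name = f"group_{lv}"
        cols[name] = (groups == lv).astype(float).to_numpy()
        group_cols.append(name)
    X = pd.DataFrame(cols, index=samples.index)
    if omega is not None:
        omega = omega.loc[samples.index]
        keep = list(omega.columns)
        if drop_omega_column is None:
            if np.allclose(omega.sum(axis=1), 1.0):
                raise DesignError(
                    "full omega block plus intercept is collinear; drop one column"
                )
        else:
            dropped = keep.pop(drop_omega_column if drop_omega_column >= 0 else len(keep) - 1)
            log.debug("omega column %s dropped from the design", dropped)
        for c in keep:
            X[f"omega_{c}"] = omega[c].to_numpy()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError(f"design matrix is rank deficient; columns: {list(X.columns)}")
    return DesignMatrix(
        matrix=X, groups=groups, reference_group=reference_group, group_columns=group_cols
    )


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of residual variances (method of moments).

    Returns (d0, s02, posterior s2).  When the dispersion of log s2 does not
    exceed what sampling alone explains, d0 is infinite and s02 is the
    geometric mean of the s2, which makes the moderation an exact no-op for
    a constant variance vector.
    """
    s2 = np.maximum(np.asarray(s2, float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(z))), np.full_like(s2, np.exp(np.mean(z)))
    # invert trigamma to get d0/2
    target = evar

    def f(x):
        return special.polygamma(1, x) - target

    lo, hi = 1e-6, 1e6
    x = optimize.brentq(f, lo, hi)
    d0 = 2 * x
    s02 = float(np.exp(np.mean(e) + special.digamma(x) - np.log(x)))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return d0, s02, post


def fit_probe_models(
    m_matrix: pd.DataFrame,
    design: DesignMatrix,
    contrasts: dict[str, tuple[str | None, str | None]] | None = None,
    moderated: bool = True,
) -> pd.DataFrame:
    """OLS per probe with optional empirical-Bayes moderation.

    ``contrasts`` maps a contrast label to (group2, group1) meaning the
    effect group2 - group1; ``None`` stands for the reference group.  The
    default contrasts every non-reference group against the reference and
    successive groups against each other.  Returns a long table indexed by
    (probe_id, contrast) with coefficient, t, p and the adjustment
    coefficients.
    """
    X = design.matrix.to_numpy(float)
    if not m_matrix.columns.equals(design.matrix.index):
        m_matrix = m_matrix[design.matrix.index]
    Y = m_matrix.to_numpy(float)  # probes x samples
    n, p = X.shape
    df_resid = n - p
    if df_resid < 2:
        raise DesignError("need at least 2 residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = Y @ X @ xtx_inv  # probes x p
    resid = Y - coefs @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid

    if moderated:
        d0, s02, post_s2 = _squeeze_var(s2, df_resid)
        df_total = d0 + df_resid
    else:
        post_s2 = s2
        df_total = float(df_resid)

    if contrasts is None:
        contrasts = _default_contrasts(design)
    colpos = {c: i for i, c in enumerate(design.matrix.columns)}

    frames = []
    for label, (g2, g1) in contrasts.items():
        cvec = np.zeros(p)
        for g, sign in ((g2, 1.0), (g1, -1.0)):
            if g is None or g == design.reference_group:
                continue
            name = f"group_{g}"
            if name not in colpos:
                raise DesignError(f"contrast group {g!r} missing from the design")
            cvec[colpos[name]] += sign
        var_c = float(cvec @ xtx_inv @ cvec)
        effect = coefs @ cvec
        se = np.sqrt(post_s2 * var_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / se
        # zero residual variance: infinite evidence for a nonzero effect
        t = np.where(se > 0, t, np.where(effect == 0, 0.0, np.sign(effect) * np.inf))
        if np.isinf(df_total):
            pvals = 2 * stats.norm.sf(np.abs(t))
        else:
            pvals = 2 * stats.t.sf(np.abs(t), df_total)
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": m_matrix.index,
                    "contrast": label,
                    "coef": effect,
                    "t": t,
                    "p": pvals,
                    "s2": s2,
                    "post_s2": post_s2,
                    "df": df_total,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    adj_cols = [c for c in design.matrix.columns if c.startswith("omega_")]
    for c in adj_cols:
        out[c] = np.tile(coefs[:, colpos[c]], len(contrasts))
    return out.set_index(["probe_id", "contrast"])


def _default_contrasts(design: DesignMatrix) -> dict[str, tuple[str | None, str | None]]:
    levels = [c.removeprefix("group_") for c in design.group_columns]
    ref = design.reference_group
    out = {f"{lv}_vs_{ref}": (lv, None) for lv in levels}
    for a, b in zip(levels[1:], levels[:-1]):
        out[f"{a}_vs_{b}"] = (a, b)
    return out


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_delta_beta(
    betas: pd.DataFrame, groups: pd.Series, contrast: tuple[str, str]
) -> pd.Series:
    """mean(beta | group2) - mean(beta | group1) on raw normalized betas.

    ``contrast`` is (group1, group2): the second-named group's mean minus
    the first's, matching the ``<g2>_vs_<g1>`` contrast labels.
    """
    g1, g2 = contrast
    groups = groups.astype(str)
    idx1 = groups.index[groups == g1]
    idx2 = groups.index[groups == g2]
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError(f"empty group in contrast {contrast}")
    return betas[idx2].mean(axis=1) - betas[idx1].mean(axis=1)


def call_dmps(
    stats_table: pd.DataFrame,
    delta_beta: pd.Series,
    q_thresh: float = 0.05,
    db_thresh: float = 0.05,
) -> pd.DataFrame:
    """Joint criterion: DMP iff q < q_thresh and |delta beta| > db_thresh.

    Both inequalities are strict, so boundary values are excluded.  The
    input must be the per-probe statistics of a single contrast with a ``p``
    column; q is (re)computed here by BH so the table is self-contained.
    """
    table = stats_table.copy()
    if not table.index.equals(delta_beta.index):
        missing = table.index.difference(delta_beta.index)
        if len(missing):
            raise ValueError(f"delta beta missing for probes such as {list(missing[:3])}")
        delta_beta = delta_beta.loc[table.index]
    table["q"] = adjust_fdr(table["p"].to_numpy())
    table["delta_beta"] = delta_beta
    table["is_dmp"] = (table["q"] < q_thresh) & (table["delta_beta"].abs() > db_thresh)
    table["direction"] = np.where(table["delta_beta"] >= 0, "hyper", "hypo")
    return table.sort_values("q")


def map_dmps_to_genes(dmp_table: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Genes with >= 1 DMP, directed by the majority of their member DMPs.

    Probes mapping to multiple genes (';'-separated) count for each; ties
    break by the direction of the member DMP with the smallest q.
    Unannotated DMPs are counted in the log and skipped.
    """
    dmps = dmp_table[dmp_table["is_dmp"]]
    gene_lists = annotation["gene"].astype(str).str.split(";")
    records: dict[str, list[tuple[float, str, str]]] = {}
    n_unannotated = 0
    for probe in dmps.index:
        genes = gene_lists.get(probe)
        if genes is None or genes in ([""], ["nan"]):
            n_unannotated += 1
            continue
        row = dmps.loc[probe]
        for gene in genes:
            records.setdefault(gene, []).append((row["q"], row["direction"], probe))
    if n_unannotated:
        log.info("%d DMPs without gene annotation skipped", n_unannotated)
    rows = []
    for gene, members in records.items():
        n_hyper = sum(1 for _, d, _ in members if d == "hyper")
        n_hypo = len(members) - n_hyper
        if n_hyper != n_hypo:
            direction = "hyper" if n_hyper > n_hypo else "hypo"
        else:
            direction = min(members)[1]  # tie: smallest q decides
        rep = min(members)[2]
        rows.append(
            {
                "gene": gene,
                "n_dmps": len(members),
                "n_hyper": n_hyper,
                "n_hypo": n_hypo,
                "direction": direction,
                "representative_probe": rep,
                "min_q": min(members)[0],
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene", "n_dmps", "n_hyper", "n_hypo", "direction", "representative_probe", "min_q"],
    )
    return out.set_index("gene").sort_values("min_q")


def mds_coordinates(
    betas: pd.DataFrame, n_top: int = 1000, n_components: int = 6
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) MDS on the most variable probes.

    Double-centres the squared Euclidean sample distances and
    eigendecomposes; variance explained is eigenvalue over the sum of
    positive eigenvalues.  Components beyond samples - 1 are truncated with
    a warning.
    """
    n_samples = betas.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples for MDS")
    if n_components > n_samples - 1:
        log.warning("n_components truncated to %d", n_samples - 1)
        n_components = n_samples - 1
    var = betas.var(axis=1)
    top = var.nlargest(min(n_top, len(var))).index
    x = betas.loc[top].to_numpy().T  # samples x probes
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    j = np.eye(n_samples) - np.ones((n_samples, n_samples)) / n_samples
    b = -0.5 * j @ sq @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0, None)
    coords = vecs[:, :n_components] * np.sqrt(pos[:n_components])
    var_explained = pos[:n_components] / pos.sum() if pos.sum() > 0 else pos[:n_components]
    frame = pd.DataFrame(
        coords,
        index=betas.columns,
        columns=[f"MDS{i + 1}" for i in range(n_components)],
    )
    return frame, var_explained
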