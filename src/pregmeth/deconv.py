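"""Reference-free cell-type deconvolution of a beta matrix.

Factorizes betas (probes x samples) as Mu @ Omega^T with Mu in [0, 1]
(latent cell-type methylomes) and Omega rows on the probability simplex
(per-sample mixing proportions), in the spirit of constrained non-negative
matrix factorization for methylation mixtures.  The number of cell types K
is selected as the value minimizing the variance of the bootstrapped
deviance (residual sum of squares), bootstrapping samples with probes fixed.

Both half-updates of the alternating scheme are solved exactly — bounded
least squares for Mu rows via active-set enumeration, simplex-constrained
least squares for Omega rows via support enumeration — so the deviance is
non-increasing over iterations by construction.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class MixtureDecomposition:
    mu: pd.DataFrame  # probes x K, entries in [0, 1]
    omega: pd.DataFrame  # samples x K, rows on the simplex
    k: int
    deviance: float
    n_iter: int
    converged: bool
    seed: int
    deviance_trace: list[float] = field(default_factory=list)

    def per_sample_rss(self, betas: pd.DataFrame) -> pd.Series:
        resid = betas.to_numpy() - self.mu.to_numpy() @ self.omega.to_numpy().T
        return pd.Series((resid**2).sum(axis=0), index=self.omega.index)


def _simplex_lsq(mu: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact min ||b - Mu w||^2 s.t. w >= 0, sum w = 1, for all columns of b.

    Enumerates nonempty support sets; for each, solves the equality-
    constrained KKT system for all samples at once and keeps the feasible
    candidate with the lowest objective.  Exact for the small K used here.
    """
    k = mu.shape[1]
    n = b.shape[1]
    gram = mu.T @ mu
    mtb = mu.T @ b  # k x n
    best_obj = np.full(n, np.inf)
    best_w = np.zeros((k, n))
    for r in range(1, k + 1):
        for support in itertools.combinations(range(k), r):
            s = list(support)
            # KKT: [G_ss 1; 1^T 0] [w; lam] = [Mu_s^T b; 1]
            kkt = np.zeros((r + 1, r + 1))
            kkt[:r, :r] = gram[np.ix_(s, s)]
            kkt[:r, r] = 1.0
            kkt[r, :r] = 1.0
            rhs = np.vstack([mtb[s], np.ones(n)])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            w_s = sol[:r]
            feasible = (w_s >= -1e-10).all(axis=0)
            if not feasible.any():
                continue
            w_full = np.zeros((k, n))
            w_full[s] = np.clip(w_s, 0.0, None)
            w_full /= w_full.sum(axis=0, keepdims=True)
            obj = ((mu @ w_full - b) ** 2).sum(axis=0)
            better = feasible & (obj < best_obj - 1e-15)
            best_obj[better] = obj[better]
            best_w[:, better] = w_full[:, better]
    return best_w


def _bounded_lsq_rows(omega: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact min ||b_i - Omega m_i||^2 s.t. m_i in [0,1]^K, for every row of b.

    Active-set enumeration over the 3^K bound patterns (free / at 0 / at 1);
    each pattern is solved for all probes at once.
    """
    k = omega.shape[1]
    n = b.shape[0]
    gram = omega.T @ omega
    bt = b @ omega  # n x k
    best_obj = np.full(n, np.inf)
    best_m = np.zeros((n, k))
    for pattern in itertools.product((0, 1, 2), repeat=k):  # 0 free, 1 at 0, 2 at 1
        free = [i for i, p in enumerate(pattern) if p == 0]
        at_one = [i for i, p in enumerate(pattern) if p == 2]
        fixed = np.zeros(k)
        fixed[at_one] = 1.0
        rhs = bt[:, free].T - gram[np.ix_(free, at_one)] @ np.ones((len(at_one), n)) if free else None
        m_full = np.tile(fixed, (n, 1))
        if free:
            g_ff = gram[np.ix_(free, free)]
            try:
                sol = np.linalg.solve(g_ff, rhs)
            except np.linalg.LinAlgError:
                continue
            feasible = ((sol >= -1e-10) & (sol <= 1 + 1e-10)).all(axis=0)
            if not feasible.any():
                continue
            m_full[:, free] = np.clip(sol.T, 0.0, 1.0)
        else:
            feasible = np.ones(n, bool)
        obj = ((omega @ m_full.T - b.T) ** 2).sum(axis=0)
        better = feasible & (obj < best_obj - 1e-15)
        best_obj[better] = obj[better]
        best_m[better] = m_full[better]
    return best_m


def _anchor(mu: np.ndarray, omega: np.ndarray, n_cycles: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Canonicalize the factorization by expanding the profile simplex.

    The product Mu @ Omega^T only identifies Mu and Omega up to an affine
    re-parameterization of the mixing simplex, so the fit alone cannot pin
    the scale of the proportions.  This picks the representation whose
    profile vertices are pushed outward (away from the centroid of the
    others) until the [0, 1] bounds on Mu bind — the maximum-volume simplex
    inscribed in the feasible box.  With cell-type-specific CpGs near full
    methylation contrast this is the biologically meaningful representation.
    The reconstruction Mu @ Omega^T is preserved exactly.
    """
    mu = mu.copy()
    omega = omega.copy()
    k = mu.shape[1]
    if k < 2:
        return mu, omega
    for _ in range(n_cycles):
        moved = 0.0
        for i in range(k):
            others = [j for j in range(k) if j != i]
            c = mu[:, others].mean(axis=1)
            d = mu[:, i] - c
            # max s >= 0 with mu_i + s*d within [0, 1]
            with np.errstate(divide="ignore", invalid="ignore"):
                hi = np.where(d > 1e-12, (1.0 - mu[:, i]) / d, np.inf)
                lo = np.where(d < -1e-12, (0.0 - mu[:, i]) / d, np.inf)
            s = float(min(np.min(hi), np.min(lo)))
            if not np.isfinite(s) or s <= 1e-9:
                continue
            s = max(s, 0.0)
            mu[:, i] = mu[:, i] + s * d
            w_i = omega[:, i] / (1.0 + s)
            omega[:, i] = w_i
            omega[:, others] += (w_i * s / (k - 1))[:, None]
            moved += s
        if moved < 1e-9:
            break
    return mu, omega


def reffree_decompose(
    betas: pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-7,
    n_restarts: int = 5,
    anchor: bool = True,
) -> MixtureDecomposition:
    """Alternating constrained least squares; multiple restarts keep the best.

    Deviance is the residual sum of squares of the factorization.  Both
    half-updates are exact minimizations, so the recorded deviance trace is
    non-increasing.  ``anchor`` canonicalizes the returned representation
    (see :func:`_anchor`) without changing the fit.
    """
    b = betas.to_numpy(float)
    n_probes, n_samples = b.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({n_samples})")
    if np.ptp(b) == 0 and k > 1:
        warnings.warn("all-constant beta matrix: returning duplicated profile")
        mu = np.full((n_probes, k), b.flat[0])
        omega = np.full((n_samples, k), 1.0 / k)
        return _wrap(betas, mu, omega, k, 0.0, 0, True, seed, [0.0])

    root = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        rng = np.random.default_rng(root.integers(2**31))
        omega = rng.dirichlet(np.ones(k), size=n_samples)
        trace: list[float] = []
        converged = False
        it = 0
        mu = None
        for it in range(1, max_iter + 1):
            mu = _bounded_lsq_rows(omega, b)
            omega = _simplex_lsq(mu, b).T
            dev = float(((b - mu @ omega.T) ** 2).sum())
            trace.append(dev)
            if len(trace) > 1 and trace[-2] - dev < tol * (trace[-2] + 1e-12):
                converged = True
                break
        dev = trace[-1]
        if best is None or dev < best[0] - 1e-15:
            best = (dev, mu, omega, it, converged, trace)
    dev, mu, omega, it, converged, trace = best
    if anchor:
        mu, omega = _anchor(mu, omega)
    return _wrap(betas, mu, omega, k, dev, it, converged, seed, trace)


def _wrap(betas, mu, omega, k, dev, n_iter, converged, seed, trace) -> MixtureDecomposition:
    cols = [f"celltype_{i}" for i in range(k)]
    return MixtureDecomposition(
        mu=pd.DataFrame(mu, index=betas.index, columns=cols),
        omega=pd.DataFrame(omega, index=betas.columns, columns=cols),
        k=k,
        deviance=dev,
        n_iter=n_iter,
        converged=converged,
        seed=seed,
        deviance_trace=trace,
    )


@dataclass
class KSelection:
    selected_k: int
    table: pd.DataFrame  # rows: k, columns: bootstrap deviances
    criterion: str
    fits: dict[int, MixtureDecomposition] = field(default_factory=dict)


def select_k(
    betas: pd.DataFrame,
    k_range=range(1, 5),
    n_boot: int = 10,
    seed: int = 0,
    criterion: str = "variance",
    n_restarts: int = 3,
    boot_max_iter: int = 60,
) -> KSelection:
    """Pick K minimizing the variance of the bootstrapped deviance.

    For each K the model is fitted on the full matrix (kept for audit); each
    bootstrap then resamples samples with replacement (probes fixed) and
    refits cold from a random start, recording the deviance.  Under- and
    over-parameterized fits are unstable across resamples (structured
    residuals, respectively non-identifiable extra components), which
    inflates the bootstrap variance; the true K gives a homogeneous residual
    and the most stable deviance.  ``criterion='mean'`` selects by the
    bootstrap mean instead.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty k_range")
    if not set(k_range) <= set(range(1, 11)):
        raise ValueError("k_range must lie within [1, 10]")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    b = betas.to_numpy(float)
    n_samples = b.shape[1]
    root = np.random.default_rng(seed)
    fit_seed = int(root.integers(2**31))
    boot_idx = [root.integers(0, n_samples, size=n_samples) for _ in range(n_boot)]

    rows = {}
    fits = {}
    for k in k_range:
        fits[k] = reffree_decompose(betas, k, seed=fit_seed, n_restarts=n_restarts)
        devs = []
        for i, idx in enumerate(boot_idx):
            bb = pd.DataFrame(b[:, idx])
            boot_fit = reffree_decompose(
                bb, k, seed=fit_seed + i + 1, n_restarts=1, max_iter=boot_max_iter
            )
            devs.append(boot_fit.deviance)
        rows[k] = devs
    table = pd.DataFrame.from_dict(rows, orient="index", columns=[f"boot_{i}" for i in range(n_boot)])
    table.index.name = "k"
    stat = table.var(axis=1, ddof=1) if criterion == "variance" else table.mean(axis=1)
    selected = int(stat.idxmin())
    log.info("select_k: %s of bootstrapped deviance minimized at k=%d", criterion, selected)
    return KSelection(selected_k=selected, table=table, criterion=criterion, fits=fits)


def validate_against_reference(omega_column, measured_fractions) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of inferred vs measured fractions."""
    x = np.asarray(omega_column, float)
    y = np.asarray(measured_fractions, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
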