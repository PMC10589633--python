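"""Splicing-outlier detection (SPOT-style).

Per junction cluster: fit a Dirichlet-Multinomial (DM) to the individuals'
junction counts, measure each individual's deviation from the population
splicing pattern with a Mahalanobis distance on junction proportions, and
convert distances to empirical p-values against random draws from the
fitted DM at the individual's own sequencing depth (distance distributions
depend on both cluster dimensionality and depth, so the null is simulated
per depth class rather than taken from a chi-square).

Cluster p-values map to genes through

    P_gene = 1 - (1 - p_m)^c

where p_m is the minimum p across the gene's c clusters — the probability
of seeing a minimum that small among c independent uniforms. Gene p-values
convert to non-negative Z-scores via the upper-tail normal quantile;
splicing outliers carry no direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, psi
from scipy.stats import norm


def filter_junctions(counts: pd.DataFrame, min_max_reads: int = 15,
                     min_fraction: float = 0.4,
                     fraction_reads: int = 3) -> pd.DataFrame:
    """Drop low-information junctions from a cluster count matrix.

    A junction (column) is removed when no sample reaches
    ``min_max_reads`` reads, or when fewer than ``min_fraction`` of samples
    have more than ``fraction_reads`` reads. Rows are individuals.
    """
    X = counts.to_numpy()
    keep = (X.max(axis=0) >= min_max_reads) & \
           ((X > fraction_reads).mean(axis=0) >= min_fraction)
    return counts.loc[:, counts.columns[keep]]


@dataclass
class DMFit:
    alpha: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    @property
    def concentration(self) -> float:
        return float(self.alpha.sum())

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()


def dm_log_likelihood(counts: np.ndarray, alpha: np.ndarray) -> float:
    """Dirichlet-Multinomial log-likelihood, summed over rows with depth > 0
    (the multinomial coefficient is omitted — constant in alpha)."""
    X = np.asarray(counts, float)
    alpha = np.asarray(alpha, float)
    n = X.sum(axis=1)
    pos = n > 0
    X = X[pos]
    n = n[pos]
    A = alpha.sum()
    return float(np.sum(gammaln(A) - gammaln(A + n))
                 + np.sum(gammaln(X + alpha) - gammaln(alpha)))


def _moment_init(counts: np.ndarray) -> np.ndarray:
    X = np.asarray(counts, float)
    n = X.sum(axis=1)
    pos = n > 0
    p = X[pos] / n[pos, None]
    pbar = p.mean(axis=0)
    pbar = np.clip(pbar, 1e-6, None)
    pbar /= pbar.sum()
    v = p.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = pbar * (1 - pbar) / v - 1.0
    a = a[np.isfinite(a) & (a > 0)]
    A0 = float(np.median(a)) if a.size else 10.0
    return np.clip(pbar * max(A0, 0.5), 1e-3, None)


def fit_dm(counts: pd.DataFrame | np.ndarray, tol: float = 1e-8,
           max_iter: int = 500) -> DMFit:
    """Maximum-likelihood DM fit via Minka's fixed-point iteration.

    Requires >= 2 junctions and >= 10 individuals with positive depth.
    Convergence: relative log-likelihood change below ``tol``.
    """
    X = counts.to_numpy(float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 junctions to fit a DM")
    n = X.sum(axis=1)
    if (n > 0).sum() < 10:
        raise ValueError("need at least 10 individuals with positive depth")
    if np.any(X[n > 0].sum(axis=0) == 0):
        raise ValueError("all-zero junction; filter junctions first")
    Xp = X[n > 0]
    npos = n[n > 0]
    alpha = _moment_init(X)
    ll = dm_log_likelihood(Xp, alpha)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = alpha.sum()
        num = np.sum(psi(Xp + alpha) - psi(alpha), axis=0)
        den = np.sum(psi(npos + A) - psi(A))
        alpha_new = alpha * num / den
        alpha_new = np.clip(alpha_new, 1e-10, None)
        ll_new = dm_log_likelihood(Xp, alpha_new)
        if ll_new < ll:            # fixed point overshoot: damp
            alpha_new = 0.5 * (alpha + alpha_new)
            ll_new = dm_log_likelihood(Xp, alpha_new)
            if ll_new < ll:
                break
        rel = abs(ll_new - ll) / (1.0 + abs(ll))
        alpha, ll = alpha_new, ll_new
        if rel < tol:
            converged = True
            break
    return DMFit(alpha=alpha, loglik=ll, converged=converged, n_iter=it)


def _proportion_covariance(alpha: np.ndarray, depth: float) -> np.ndarray:
    """Covariance of the junction-proportion vector x/n when x ~ DM(alpha, n)."""
    A = alpha.sum()
    mu = alpha / A
    f = (depth + A) / (depth * (1.0 + A))
    return f * (np.diag(mu) - np.outer(mu, mu))


def mahalanobis(counts_row: np.ndarray, fit: DMFit) -> float:
    """Mahalanobis distance of one individual's junction proportions from
    the DM mean, under the DM proportion covariance at that individual's
    depth. The last junction coordinate is dropped (proportions live on a
    simplex, so the full covariance is singular)."""
    x = np.asarray(counts_row, float)
    depth = x.sum()
    if depth < 1:
        raise ValueError("individual depth must be >= 1")
    p = x / depth
    mu = fit.mean
    cov = _proportion_covariance(fit.alpha, depth)[:-1, :-1]
    d = (p - mu)[:-1]
    try:
        sol = np.linalg.solve(cov, d)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular DM proportion covariance (alpha={fit.alpha})") from err
    md2 = float(d @ sol)
    return float(np.sqrt(max(md2, 0.0)))


def _mahalanobis_many(X: np.ndarray, fit: DMFit) -> np.ndarray:
    """Vectorized MD for rows sharing arbitrary depths; NaN for depth 0."""
    X = np.asarray(X, float)
    depths = X.sum(axis=1)
    out = np.full(X.shape[0], np.nan)
    pos = depths > 0
    if not np.any(pos):
        return out
    A = fit.concentration
    mu = fit.mean
    S = np.diag(mu) - np.outer(mu, mu)
    S_red = S[:-1, :-1]
    S_inv = np.linalg.inv(S_red)
    P = X[pos] / depths[pos, None]
    D = (P - mu)[:, :-1]
    base = np.einsum("ij,jk,ik->i", D, S_inv, D)
    f = (depths[pos] + A) / (depths[pos] * (1.0 + A))
    out[pos] = np.sqrt(np.clip(base / f, 0.0, None))
    return out


def empirical_pvalues(counts: pd.DataFrame, fit: DMFit,
                      n_samples: int = 10000, seed: int = 0) -> pd.Series:
    """Empirical p-value per individual against the fitted DM null.

    For each depth class present in the cluster, ``n_samples`` DM count
    vectors are drawn at that depth and scored with the same Mahalanobis
    distance; p = (1 + #{null MD >= observed MD}) / (n_samples + 1), so the
    smallest achievable p is 1/(n_samples+1) and p never reaches 0.
    Individuals with zero depth are returned as NaN.
    """
    if n_samples < 100:
        warnings.warn("n_samples < 100 gives very coarse empirical p-values")
    from .simulate import sample_dirichlet_multinomial

    X = counts.to_numpy(float)
    depths = X.sum(axis=1).astype(int)
    md_obs = _mahalanobis_many(X, fit)
    rng = np.random.default_rng(seed)
    pvals = np.full(len(depths), np.nan)
    for depth in np.unique(depths):
        if depth == 0:
            continue
        sel = depths == depth
        null_counts = sample_dirichlet_multinomial(
            fit.alpha, np.full(n_samples, depth), rng)
        md_null = np.sort(_mahalanobis_many(null_counts, fit))
        # count of null MDs >= observed via searchsorted on the sorted null
        n_ge = n_samples - np.searchsorted(md_null, md_obs[sel], side="left")
        pvals[sel] = (1.0 + n_ge) / (n_samples + 1.0)
    return pd.Series(pvals, index=counts.index, name="p_cluster")


def gene_level_pvalue(cluster_pvalues) -> tuple[float, int, float]:
    """Aggregate cluster p-values for one (gene, individual).

    Returns (p_m, c, P_gene) with p_m the minimum cluster p, c the number
    of clusters, and P_gene = 1 - (1 - p_m)^c.
    """
    ps = np.asarray([p for p in cluster_pvalues if not np.isnan(p)], float)
    if ps.size == 0:
        return (np.nan, 0, np.nan)
    p_m = float(ps.min())
    c = int(ps.size)
    return (p_m, c, float(1.0 - (1.0 - p_m) ** c))


def pvalue_to_z(p) -> np.ndarray:
    """One-sided upper-tail normal quantile, floored at 0: Z = max(0, Phi^-1(1-p)).

    Splicing outliers carry no direction, so Z is reported non-negative.
    """
    p = np.asarray(p, float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return np.maximum(norm.isf(p), 0.0)


def spot_gene_scores(clusters, n_samples: int = 10000, seed: int = 0) -> pd.DataFrame:
    """End-to-end SPOT over a list of clusters.

    Each cluster is a dict with keys ``counts`` (individuals x junctions
    DataFrame), ``gene`` and ``cluster_id``. Junction filters are applied;
    clusters left with < 2 junctions or a non-converged DM fit are skipped.
    Returns a tidy frame with gene, individual, p_m, c, p_gene, z.
    """
    per_cluster = {}
    for i, clu in enumerate(clusters):
        counts = filter_junctions(clu["counts"])
        if counts.shape[1] < 2:
            continue
        try:
            fit = fit_dm(counts)
        except ValueError:
            continue
        if not fit.converged:
            continue
        p = empirical_pvalues(counts, fit, n_samples=n_samples, seed=seed + i)
        per_cluster.setdefault(clu["gene"], []).append(p)
    rows = []
    for gene, series_list in per_cluster.items():
        mat = pd.concat(series_list, axis=1)
        for ind, ps in mat.iterrows():
            p_m, c, p_gene = gene_level_pvalue(ps.to_numpy())
            if c == 0:
                continue
            rows.append((gene, ind, p_m, c, p_gene,
                         float(pvalue_to_z(p_gene))))
    return pd.DataFrame(rows, columns=["gene", "individual", "p_m", "c",
                                       "p_gene", "z"])
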