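"""Residual Z-scores and joint outlier calling across two exams.

Raw molecular matrices (features x individuals; log2(TPM+2) expression,
methylation beta values, log protein fluorescence) are residualized on
covariates per feature, scaled to Z within each exam, and (feature,
individual) pairs are called outliers only when the signal is present in
both exams ~10 years apart — the longitudinal design's guard against
technical one-offs.

Status vocabulary: over_outlier / under_outlier (|Z| above threshold in
both exams, consistent sign), control (|Z| < 1 in both exams), neither,
missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STATUS_OVER = "over_outlier"
STATUS_UNDER = "under_outlier"
STATUS_CONTROL = "control"
STATUS_NEITHER = "neither"
STATUS_MISSING = "missing"


def filter_expression_matrix(matrix: pd.DataFrame, raw_counts: pd.DataFrame,
                             tpm: pd.DataFrame, min_reads: int = 6,
                             min_tpm: float = 0.1,
                             min_fraction: float = 0.2) -> pd.DataFrame:
    """Keep genes with >= min_reads reads AND TPM > min_tpm in at least
    ``min_fraction`` of individuals (boundaries inclusive for reads and the
    fraction, exclusive for TPM)."""
    if not matrix.index.equals(raw_counts.index) or not matrix.index.equals(tpm.index):
        raise ValueError("counts/TPM must align with matrix features")
    ok = (raw_counts >= min_reads) & (tpm > min_tpm)
    frac = ok.mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise ValueError(
            f"no genes pass the expression filter (>= {min_reads} reads and "
            f"TPM > {min_tpm} in >= {min_fraction:.0%} of individuals)"
        )
    return matrix.loc[keep]


def mvalue_transform(beta):
    """m = log2(beta / (1 - beta)) for methylation beta in (0, 1)."""
    beta = np.asarray(beta, float)
    if np.any(beta <= 0) or np.any(beta >= 1):
        raise ValueError("beta values must lie strictly inside (0, 1)")
    return np.log2(beta / (1.0 - beta))


def mvalue_inverse(m):
    """Inverse of the m-value transform: beta = 2^m / (1 + 2^m)."""
    m = np.asarray(m, float)
    return 1.0 / (1.0 + 2.0 ** (-m))


def estimate_hidden_factors(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Latent technical factors via truncated SVD of the centered matrix.

    Returns individuals x k orthonormal factor columns ordered by
    decreasing explained variance. These play the role hidden-factor
    methods (e.g. PEER) play in covariate correction.
    """
    X = matrix.to_numpy(float)
    if k > min(X.shape) - 1:
        raise ValueError(f"k={k} exceeds min(n_features, n_individuals) - 1")
    Xc = X - X.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    return pd.DataFrame(vt[:k].T, index=matrix.columns,
                        columns=[f"factor{i+1}" for i in range(k)])


def _collinear_columns(X: np.ndarray, names) -> list:
    from scipy.linalg import qr
    _, r, piv = qr(X, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def residualize_and_scale(matrix: pd.DataFrame, covariates: pd.DataFrame,
                          qtl: pd.DataFrame | None = None,
                          min_n: int = 30) -> pd.DataFrame:
    """Per-feature OLS residuals on the covariates, scaled to Z-scores.

    covariates: individuals x c (an intercept is added). qtl optionally
    supplies one extra per-feature covariate row (features x individuals),
    e.g. the strongest cis-QTL genotype. Missing values are excluded
    pairwise; features with fewer than ``min_n`` non-missing individuals or
    zero residual variance are excluded with a warning. Scaling uses the
    sample (ddof=1) standard deviation.
    """
    inds = list(matrix.columns)
    if not set(inds) <= set(covariates.index):
        raise ValueError("covariate rows must cover all individuals")
    C = covariates.loc[inds].to_numpy(float)
    base = np.column_stack([np.ones(len(inds)), C])
    base_names = ["intercept", *covariates.columns]
    out = {}
    skipped = []
    for feat, row in matrix.iterrows():
        y = row.to_numpy(float)
        X = base
        names = base_names
        if qtl is not None and feat in qtl.index:
            X = np.column_stack([base, qtl.loc[feat, inds].to_numpy(float)])
            names = [*base_names, "qtl"]
        ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
        if ok.sum() < min_n:
            skipped.append(feat)
            continue
        Xo, yo = X[ok], y[ok]
        rank = np.linalg.matrix_rank(Xo)
        if rank < Xo.shape[1]:
            bad = _collinear_columns(Xo, names)
            raise ValueError(f"singular design for {feat}; collinear columns: {bad}")
        coef, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
        resid = yo - Xo @ coef
        sd = resid.std(ddof=1)
        if sd < 1e-12:
            skipped.append(feat)
            continue
        z = np.full(len(inds), np.nan)
        z[ok] = (resid - resid.mean()) / sd
        out[feat] = z
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} feature(s) with <{min_n} observations "
            f"or zero residual variance"
        )
    if not out:
        raise ValueError("no features could be residualized")
    return pd.DataFrame.from_dict(out, orient="index", columns=inds)


def gene_level_methylation(cpg_z: pd.DataFrame, cpg_coords: pd.DataFrame,
                           gene_tss: pd.DataFrame,
                           window: int = 1500) -> pd.DataFrame:
    """Gene-level methylation Z: median across CpGs within ``window`` bp
    upstream of the gene TSS (strand-aware; distance 0..window inclusive).

    cpg_coords: index CpG id, columns chrom, pos. gene_tss: index gene,
    columns chrom, tss, strand. Genes with no qualifying CpG get NaN rows.
    """
    missing = [c for c in cpg_z.index if c not in cpg_coords.index]
    if missing:
        raise ValueError(f"CpGs with no coordinates: {missing}")
    coords = cpg_coords.loc[cpg_z.index]
    rows = {}
    for gene, g in gene_tss.iterrows():
        on_chrom = coords["chrom"] == g["chrom"]
        if str(g.get("strand", "+")) == "-":
            dist = coords["pos"] - g["tss"]
        else:
            dist = g["tss"] - coords["pos"]
        sel = on_chrom & (dist >= 0) & (dist <= window)
        if sel.any():
            rows[gene] = cpg_z.loc[sel[sel].index].median(axis=0)
        else:
            rows[gene] = pd.Series(np.nan, index=cpg_z.columns)
    return pd.DataFrame(rows).T


@dataclass
class OutlierCallSet:
    """Joint two-exam outlier calls for one signal."""

    status: pd.DataFrame       # feature x individual status strings
    median_z: pd.DataFrame     # median-across-exam Z
    threshold: float

    def counts_per_individual(self) -> pd.Series:
        isout = self.status.isin([STATUS_OVER, STATUS_UNDER])
        return isout.sum(axis=0)


def call_joint_outliers(exam1: pd.DataFrame, exam5: pd.DataFrame,
                        threshold: float = 3.0,
                        control_threshold: float = 1.0) -> OutlierCallSet:
    """Joint outliers require |Z| > threshold in BOTH exams with a
    consistent sign; controls require |Z| < control_threshold in both."""
    if not exam1.index.equals(exam5.index) or not exam1.columns.equals(exam5.columns):
        raise ValueError("exam matrices must align on features and individuals")
    z1 = exam1.to_numpy(float)
    z2 = exam5.to_numpy(float)
    status = np.full(z1.shape, STATUS_NEITHER, dtype=object)
    miss = np.isnan(z1) | np.isnan(z2)
    over = (z1 > threshold) & (z2 > threshold)
    under = (z1 < -threshold) & (z2 < -threshold)
    control = (np.abs(z1) < control_threshold) & (np.abs(z2) < control_threshold)
    status[control] = STATUS_CONTROL
    status[over] = STATUS_OVER
    status[under] = STATUS_UNDER
    status[miss] = STATUS_MISSING
    med = np.nanmedian(np.stack([z1, z2]), axis=0)
    med[miss] = np.nan
    return OutlierCallSet(
        status=pd.DataFrame(status, index=exam1.index, columns=exam1.columns),
        median_z=pd.DataFrame(med, index=exam1.index, columns=exam1.columns),
        threshold=float(threshold),
    )


def remove_global_outliers(calls: OutlierCallSet) -> OutlierCallSet:
    """Drop individuals with anomalously many outlier calls.

    An individual is removed (all calls set missing) when their outlier
    count exceeds Q3 + 1.5*IQR of the per-individual count distribution,
    with linear-interpolation (type-7) quartiles.
    """
    counts = calls.counts_per_individual()
    if len(counts) < 2:
        return calls
    q1, q3 = np.percentile(counts.to_numpy(), [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    bad = counts.index[counts > fence]
    status = calls.status.copy()
    med = calls.median_z.copy()
    status.loc[:, bad] = STATUS_MISSING
    med.loc[:, bad] = np.nan
    return OutlierCallSet(status=status, median_z=med, threshold=calls.threshold)


def replication_rate(exam1: pd.DataFrame, exam5: pd.DataFrame,
                     call_threshold: float, replicate_threshold: float = 2.0,
                     direction: str = "both") -> float:
    """Fraction of exam-1 outliers that replicate in exam 5.

    direction 'over'/'under' restricts exam-1 calls by sign and requires the
    exam-5 value to exceed the replication threshold with the same sign;
    'both' uses |Z| in both exams.
    """
    z1 = exam1.to_numpy(float)
    z2 = exam5.to_numpy(float)
    if direction == "over":
        called = z1 > call_threshold
        repl = z2 > replicate_threshold
    elif direction == "under":
        called = z1 < -call_threshold
        repl = z2 < -replicate_threshold
    elif direction == "both":
        called = np.abs(z1) > call_threshold
        repl = np.abs(z2) > replicate_threshold
    else:
        raise ValueError("direction must be 'over', 'under' or 'both'")
    called &= ~np.isnan(z1) & ~np.isnan(z2)
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("no exam-1 outliers at this threshold; "
                         "replication rate undefined")
    return float((called & repl).sum() / n_called)


def cross_omics_sharing(calls_a: OutlierCallSet, z_b_exam1: pd.DataFrame,
                        z_b_exam5: pd.DataFrame,
                        relaxed_threshold: float = 2.0) -> dict:
    """Sharing of signal-a outliers into signal b.

    Over the (feature, individual) universe measured in both signals:
    the fraction of a-outliers whose mean-across-exam |Z_b| exceeds the
    relaxed threshold, plus a one-sided Wilcoxon rank-sum test comparing
    |mean Z_b| between a-outliers and a-non-outliers.
    """
    feats = calls_a.status.index.intersection(z_b_exam1.index)
    inds = calls_a.status.columns.intersection(z_b_exam1.columns)
    if len(feats) == 0 or len(inds) == 0:
        raise ValueError("no overlapping (feature, individual) universe")
    zb = (z_b_exam1.loc[feats, inds] + z_b_exam5.loc[feats, inds]) / 2.0
    status = calls_a.status.loc[feats, inds]
    isout = status.isin([STATUS_OVER, STATUS_UNDER]).to_numpy()
    measured = ~zb.isna().to_numpy()
    out_vals = np.abs(zb.to_numpy()[isout & measured])
    null_vals = np.abs(zb.to_numpy()[
        (status == STATUS_NEITHER).to_numpy() | (status == STATUS_CONTROL).to_numpy()
    ])
    null_vals = null_vals[~np.isnan(null_vals)]
    if out_vals.size == 0:
        raise ValueError("no signal-a outliers measured in signal b")
    sharing = float((out_vals > relaxed_threshold).mean())
    stat, p = stats.mannwhitneyu(out_vals, null_vals, alternative="greater")
    return {"sharing": sharing, "statistic": float(stat), "p_value": float(p),
            "n_outliers": int(out_vals.size), "n_background": int(null_vals.size)}
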