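"""Building model inputs: annotation aggregation, standardization, outlier
binarization, and the training-instance filters.

An *instance* is one (gene, individual) pair. Its annotation vector G
aggregates the genomic annotations of all rare variants the individual
carries within the gene window (max per feature); its outlier status E is a
per-signal categorical derived from outlier p-values, with direction taken
from the sign of the median Z.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .params import MISSING

DIRECTIONAL = ("expression", "methylation", "protein")


def aggregate_annotations(variants: pd.DataFrame, annotation_cols,
                          gene_col: str = "gene",
                          carrier_col: str = "carriers") -> pd.DataFrame:
    """Aggregate variant annotations to (gene, individual) vectors.

    ``variants[carrier_col]`` holds carrier individual IDs, either as a list
    or a comma-separated string. Each annotation is aggregated with max
    across all of an individual's rare variants near the gene, which keeps
    binary flags binary and picks the strongest score for continuous ones.
    """
    missing = [c for c in annotation_cols if c not in variants.columns]
    if missing:
        raise KeyError(f"annotations absent from variant table: {missing}")
    rows = []
    for _, v in variants.iterrows():
        carriers = v[carrier_col]
        if isinstance(carriers, str):
            carriers = [c for c in carriers.split(",") if c]
        for ind in carriers:
            rows.append((v[gene_col], ind, *[v[c] for c in annotation_cols]))
    if not rows:
        return pd.DataFrame(columns=["gene", "individual", *annotation_cols]
                            ).set_index(["gene", "individual"])
    df = pd.DataFrame(rows, columns=["gene", "individual", *annotation_cols])
    return df.groupby(["gene", "individual"]).max()


def standardize_annotations(G: pd.DataFrame) -> pd.DataFrame:
    """Mean-center and scale each annotation column to unit variance.

    Uses the population (ddof=0) standard deviation. Constant columns carry
    no information and are dropped with a warning; an all-constant matrix is
    an error.
    """
    if len(G) < 2:
        raise ValueError("need at least two instances to standardize")
    mu = G.mean(axis=0)
    sd = G.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all annotation columns are constant")
    dropped = list(G.columns[~keep])
    if dropped:
        warnings.warn(f"dropping constant annotation columns: {dropped}")
    return (G.loc[:, keep] - mu[keep]) / sd[keep]


def binarize_outliers(pvalues: np.ndarray, zsigns: np.ndarray,
                      n_categories, threshold_p: float = 0.05) -> np.ndarray:
    """Map per-signal p-values (+ Z sign) to categorical outlier status.

    Directional signals (3 categories) become under (1) / over (2) when
    p < threshold using the sign of Z, else none (0); splicing (2
    categories) becomes outlier (1) / none (0). NaN p-values propagate as
    missing (-1).
    """
    p = np.atleast_2d(np.asarray(pvalues, float))
    s = np.atleast_2d(np.asarray(zsigns, float))
    obs = ~np.isnan(p)
    if np.any((p[obs] <= 0) | (p[obs] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    E = np.full(p.shape, MISSING, dtype=int)
    for k, C in enumerate(n_categories):
        col_obs = obs[:, k]
        hit = col_obs & (p[:, k] < threshold_p)
        E[col_obs, k] = 0
        if C == 2:
            E[hit, k] = 1
        else:
            E[hit & (s[:, k] < 0), k] = 1
            E[hit & (s[:, k] >= 0), k] = 2
    return E


def _iqr_fence(counts: np.ndarray) -> float:
    # linear-interpolation (type-7) quartiles
    q1, q3 = np.percentile(counts, [25, 75])
    return q3 + 1.5 * (q3 - q1)


def filter_training_instances(z_exam1: np.ndarray, z_exam2: np.ndarray,
                              genes, individuals,
                              outlier_z: float = 3.0,
                              inconsistent_low: float = 1.0):
    """Apply the training-set filters and return median Z plus a keep mask.

    Filters, in order:

    1. Per signal, drop measurements inconsistent across the two exams
       (one exam |Z| >= ``outlier_z`` while the other has |Z| <=
       ``inconsistent_low``) — these are unlikely to be genetically driven.
    2. Per signal, remove individuals with anomalously many outliers
       (count > Q3 + 1.5 IQR of the per-individual outlier-count
       distribution; "global outliers").
    3. Keep instances with at least two observed signals.
    4. Keep genes with at least one outlier individual in two or more
       signals.

    Returns (median_z, keep) where median_z is (n, K) with NaN for dropped
    measurements and keep is a boolean instance mask.
    """
    z1 = np.asarray(z_exam1, float).copy()
    z2 = np.asarray(z_exam2, float).copy()
    genes = np.asarray(genes)
    individuals = np.asarray(individuals)
    n, K = z1.shape

    both = ~np.isnan(z1) & ~np.isnan(z2)
    incons = both & (
        ((np.abs(z1) >= outlier_z) & (np.abs(z2) <= inconsistent_low))
        | ((np.abs(z2) >= outlier_z) & (np.abs(z1) <= inconsistent_low))
    )
    z1[incons] = np.nan
    z2[incons] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median_z = np.nanmedian(np.stack([z1, z2]), axis=0)

    is_outlier = np.abs(median_z) > outlier_z
    is_outlier &= ~np.isnan(median_z)
    for k in range(K):
        counts = pd.Series(is_outlier[:, k], index=individuals).groupby(level=0).sum()
        fence = _iqr_fence(counts.to_numpy())
        bad = set(counts.index[counts > fence])
        if bad:
            mask = np.isin(individuals, list(bad))
            median_z[mask, k] = np.nan
            is_outlier[mask, k] = False

    observed = (~np.isnan(median_z)).sum(axis=1)
    keep = observed >= 2

    gene_sig = pd.DataFrame(is_outlier, index=genes).groupby(level=0).any()
    good_genes = set(gene_sig.index[gene_sig.sum(axis=1) >= 2])
    keep &= np.isin(genes, list(good_genes))
    return median_z, keep
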