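"""Connecting variant posteriors to traits.

* Percentile normalization of absolute GWAS effect sizes, so effect
  distributions are comparable across prioritized variant sets.
* Distribution comparison between posterior-thresholded variant sets and
  the background (one-sided rank-sum).
* A gene-level association test: per gene, compare the distribution of
  variant posteriors carried by trait-outlier individuals (residual
  |Z| > 2) against trait-controls (residual |Z| < 0.2) with a Wilcoxon
  rank-sum test, Benjamini-Hochberg adjusted across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def percentile_normalize(effects) -> np.ndarray:
    """Map values to rank/n in (0, 1], average ranks for ties."""
    x = np.asarray(effects, float)
    if x.size == 0:
        raise ValueError("cannot percentile-normalize an empty vector")
    if x.size < 2:
        raise ValueError("need at least 2 values to percentile-normalize")
    return stats.rankdata(x, method="average") / x.size


def compare_effect_sets(background, selected) -> dict:
    """Compare normalized effects of a prioritized subset to the background.

    Returns medians of both sets and a one-sided rank-sum p-value that the
    selected effects are larger. An empty selection yields an explicit
    empty-set result instead of a test.
    """
    bg = np.asarray(background, float)
    sel = np.asarray(selected, float)
    if sel.size == 0:
        return {"n_selected": 0, "median_selected": np.nan,
                "median_background": float(np.median(bg)), "p_value": np.nan,
                "empty": True}
    stat, p = stats.mannwhitneyu(sel, bg, alternative="greater")
    return {"n_selected": int(sel.size),
            "median_selected": float(np.median(sel)),
            "median_background": float(np.median(bg)),
            "statistic": float(stat), "p_value": float(p), "empty": False}


def label_trait_individuals(residual_z: pd.Series, outlier_z: float = 2.0,
                            control_z: float = 0.2) -> pd.Series:
    """Trait labels from residual Z: outlier (|Z| > 2), control (|Z| < 0.2),
    neither otherwise."""
    z = residual_z.astype(float)
    lab = pd.Series("neither", index=z.index)
    lab[z.abs() > outlier_z] = "outlier"
    lab[z.abs() < control_z] = "control"
    return lab


def gene_posterior_association(posteriors: pd.DataFrame, labels: pd.Series,
                               signal_cols, combined_col: str = "combined",
                               min_per_group: int = 1) -> pd.DataFrame:
    """Gene-based association of variant posteriors with a trait.

    ``posteriors``: one row per (variant, gene, individual) with columns
    gene, individual and one posterior per signal. ``labels``: per
    individual, 'outlier'/'control'/'neither'. For each gene and each
    signal (plus a combined max-across-signals posterior) a one-sided
    rank-sum test asks whether posteriors in outlier individuals are
    larger; q-values are BH-adjusted across genes per signal. Genes with an
    empty group are skipped with a note column.
    """
    df = posteriors.copy()
    df["_label"] = df["individual"].map(labels)
    df = df[df["_label"].isin(["outlier", "control"])]
    if combined_col not in df.columns:
        df[combined_col] = df[list(signal_cols)].max(axis=1)
    cols = [*signal_cols, combined_col]
    rows = []
    for gene, g in df.groupby("gene"):
        out = g[g["_label"] == "outlier"]
        ctl = g[g["_label"] == "control"]
        rec = {"gene": gene, "n_outlier": len(out), "n_control": len(ctl)}
        if len(out) < min_per_group or len(ctl) < min_per_group:
            rec["note"] = "empty group"
            for c in cols:
                rec[f"p_{c}"] = np.nan
        else:
            rec["note"] = ""
            for c in cols:
                _, p = stats.mannwhitneyu(out[c], ctl[c], alternative="greater")
                rec[f"p_{c}"] = float(p)
        rows.append(rec)
    res = pd.DataFrame(rows).set_index("gene")
    for c in cols:
        p = res[f"p_{c}"]
        ok = p.notna()
        q = pd.Series(np.nan, index=res.index)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        res[f"q_{c}"] = q
    return res
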