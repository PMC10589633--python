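"""Held-out evaluation on pairs of individuals sharing a rare-variant set.

Two individuals carrying the *identical* set of rare variants near the same
gene (an "N2 pair") provide a natural held-out test: the model predicts the
regulatory status of one individual from the genomic annotations plus the
observed outlier status of the other, and is scored against the held-out
individual's own outlier labels with area under the precision-recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .inference import joint_posterior
from .params import MISSING


@dataclass
class N2Pair:
    gene: object
    held_in: object
    held_out: object
    variant_set: frozenset


def build_n2_pairs(instance_variants: pd.DataFrame) -> list:
    """Form N2 pairs from per-instance variant sets.

    ``instance_variants`` needs columns gene, individual, variants (an
    iterable of variant IDs). Individuals are paired iff their variant sets
    near the gene are identical as sets. Groups larger than two are reduced
    to the two lexicographically smallest individual IDs (held-out is the
    second), a deterministic rule.
    """
    groups: dict = {}
    for _, row in instance_variants.iterrows():
        vset = frozenset(row["variants"])
        if not vset:
            continue
        groups.setdefault((row["gene"], vset), []).append(row["individual"])
    pairs = []
    for (gene, vset), inds in groups.items():
        if len(inds) < 2:
            continue
        a, b = sorted(inds, key=str)[:2]
        pairs.append(N2Pair(gene=gene, held_in=a, held_out=b, variant_set=vset))
    pairs.sort(key=lambda p: (str(p.gene), str(p.held_in)))
    return pairs


def auc_pr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve (average precision)."""
    labels = np.asarray(labels, int)
    if labels.sum() == 0:
        raise ValueError("AUC-PR undefined without positive labels")
    return float(average_precision_score(labels, np.asarray(scores, float)))


@dataclass
class N2Evaluation:
    signal_names: tuple
    labels: np.ndarray          # (n_pairs, K) binary, -1 where missing
    watershed_scores: np.ndarray
    gam_scores: np.ndarray | None
    auc_watershed: dict
    auc_gam: dict
    bootstrap_watershed: dict   # signal -> (n_boot,) AUC-PRs
    bootstrap_gam: dict


def evaluate_n2(pairs, G_lookup, E_lookup, params, gam_coefs=None,
                min_pairs: int = 10, n_bootstrap: int = 100,
                seed: int = 0) -> N2Evaluation:
    """Score every pair and compute per-signal AUC-PR with bootstrap.

    Parameters
    ----------
    pairs : list of N2Pair
    G_lookup : callable (gene, individual) -> (P,) annotation vector
    E_lookup : callable (gene, individual) -> (K,) categorical status
    params : fitted WatershedParameters
    gam_coefs : optional (K, P+1) GAM coefficients for the baseline
    min_pairs : signals with fewer labeled pairs are skipped
    n_bootstrap : number of half-subsample bootstrap replicates
    """
    K = params.n_signals
    G_rows, E_in, E_out = [], [], []
    for p in pairs:
        G_rows.append(np.asarray(G_lookup(p.gene, p.held_out), float))
        E_in.append(np.asarray(E_lookup(p.gene, p.held_in)))
        E_out.append(np.asarray(E_lookup(p.gene, p.held_out)))
    G = np.array(G_rows)
    E_in = np.array(E_in)
    E_out = np.array(E_out)

    ws_scores = joint_posterior(G, E_in, params)        # (n_pairs, K)
    labels = np.where(E_out == MISSING, -1, (E_out > 0).astype(int))

    gam_scores = None
    if gam_coefs is not None:
        from .gam import gam_predict
        gam_scores = np.column_stack(
            [gam_predict(G, gam_coefs[k]) for k in range(K)]
        )

    rng = np.random.default_rng(seed)
    auc_ws, auc_gam, boot_ws, boot_gam = {}, {}, {}, {}
    for k, name in enumerate(params.signal_names):
        ok = labels[:, k] >= 0
        y = labels[ok, k]
        if ok.sum() < min_pairs or y.sum() == 0:
            continue
        s = ws_scores[ok, k]
        auc_ws[name] = auc_pr(y, s)
        if gam_scores is not None:
            auc_gam[name] = auc_pr(y, gam_scores[ok, k])
        bw, bg = [], []
        idx_all = np.arange(ok.sum())
        half = max(1, len(idx_all) // 2)
        for _ in range(n_bootstrap):
            idx = rng.choice(idx_all, size=half, replace=False)
            if y[idx].sum() == 0:
                continue
            bw.append(auc_pr(y[idx], s[idx]))
            if gam_scores is not None:
                bg.append(auc_pr(y[idx], gam_scores[ok, k][idx]))
        boot_ws[name] = np.array(bw)
        if gam_scores is not None:
            boot_gam[name] = np.array(bg)
    return N2Evaluation(
        signal_names=params.signal_names, labels=labels,
        watershed_scores=ws_scores, gam_scores=gam_scores,
        auc_watershed=auc_ws, auc_gam=auc_gam,
        bootstrap_watershed=boot_ws, bootstrap_gam=boot_gam,
    )


def score_all_variants(posteriors: pd.DataFrame, carriers: pd.DataFrame,
                       signal_cols) -> pd.DataFrame:
    """Per-variant posterior: max across all carriers of the variant.

    ``posteriors`` is indexed by (gene, individual) with one column per
    signal; ``carriers`` has columns variant, gene, individual. Variants
    whose carriers were never scored are absent from the result.
    """
    merged = carriers.merge(
        posteriors.reset_index(), on=["gene", "individual"], how="inner"
    )
    if merged.empty:
        return pd.DataFrame(columns=["variant", "gene", *signal_cols]
                            ).set_index("variant")
    return merged.groupby(["variant", "gene"])[list(signal_cols)].max().reset_index(
        "gene"
    )


def threshold_variant_counts(variant_posteriors: pd.DataFrame, signal_cols,
                             thresholds=(0.5, 0.9)) -> pd.DataFrame:
    """Number of variants passing each posterior cutoff, per signal."""
    rows = {
        t: {c: int((variant_posteriors[c] >= t).sum()) for c in signal_cols}
        for t in thresholds
    }
    return pd.DataFrame(rows).T
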