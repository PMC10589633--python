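"""Rare-variant burden near outliers: rarity filters, window intersection,
relative-risk estimation, enrichment comparisons, ancestry matching.

The central statistic is the relative risk from a 2x2 table of (gene,
individual) instances classified by outlier status (outlier vs control)
and rare-variant carriage:

    RR = [a / (a+b)] / [c / (c+d)]

with a Wald interval on log RR (SE = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))
and a one-sided t test of log RR / SE against RR = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def flag_rare_variants(table: pd.DataFrame, threshold: float = 0.01,
                       cohort_col: str = "af_cohort",
                       external_col: str = "af_gnomad",
                       subpop_cols=None) -> pd.DataFrame:
    """Retain variants rare everywhere: cohort AF, external overall AF and
    every listed subpopulation AF all strictly below ``threshold``.

    Missing external frequencies are treated as 0 (variant absent from the
    reference panel) with a logged note. Malformed frequencies (outside
    [0, 1]) raise with the offending row labels.
    """
    if subpop_cols is None:
        subpop_cols = [c for c in table.columns if c.startswith("af_sub_")]
    cols = [cohort_col, external_col, *subpop_cols]
    freq = table[cols].copy()
    n_missing = int(freq[[external_col, *subpop_cols]].isna().sum().sum())
    if n_missing:
        log.info("treating %d missing external frequencies as 0", n_missing)
        freq[[external_col, *subpop_cols]] = freq[
            [external_col, *subpop_cols]].fillna(0.0)
    bad = freq.index[((freq < 0) | (freq > 1) | freq.isna()).any(axis=1)]
    if len(bad):
        raise ValueError(f"malformed allele frequencies in rows: {list(bad)}")
    keep = (freq < threshold).all(axis=1)
    return table.loc[keep]


def rare_variant_indicator(variants: pd.DataFrame, windows: pd.DataFrame,
                           flank: int = 10_000,
                           carrier_col: str = "carriers") -> pd.DataFrame:
    """Binary (feature, individual) matrix: 1 iff the individual carries at
    least one retained rare variant inside the feature's window.

    ``windows``: index = feature, columns chrom, start, end (0-based
    half-open); the window is extended by ``flank`` bp on both sides.
    ``variants`` needs chrom, pos and a carrier list/comma-string column.
    """
    if (windows["end"] < windows["start"]).any():
        bad = windows.index[windows["end"] < windows["start"]]
        raise ValueError(f"windows with end < start: {list(bad)}")
    all_inds = sorted({
        i for carriers in variants[carrier_col]
        for i in (carriers.split(",") if isinstance(carriers, str) else carriers)
        if i
    })
    out = pd.DataFrame(0, index=windows.index, columns=all_inds, dtype=int)
    for feat, w in windows.iterrows():
        lo = w["start"] - flank
        hi = w["end"] + flank
        sel = (variants["chrom"] == w["chrom"]) & \
              (variants["pos"] >= lo) & (variants["pos"] < hi)
        for carriers in variants.loc[sel, carrier_col]:
            if isinstance(carriers, str):
                carriers = [c for c in carriers.split(",") if c]
            out.loc[feat, list(carriers)] = 1
    return out


@dataclass
class ContingencyTable:
    """a: outlier-with-variant, b: outlier-without, c: control-with,
    d: control-without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError("contingency cells must be non-negative integers")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise ValueError("both outlier and control margins must be non-empty")


@dataclass
class EnrichmentResult:
    relative_risk: float
    ci_low: float
    ci_high: float
    p_value: float
    se_log_rr: float
    n_outlier: int
    n_control: int
    zero_cell: bool

    @property
    def df(self) -> int:
        return self.n_outlier + self.n_control - 2


def relative_risk(table: ContingencyTable) -> EnrichmentResult:
    """Relative risk with 95% log-normal CI and one-sided t p-value vs RR=1.

    Zero a or c leaves the CI/SE undefined; the result is returned with an
    explicit zero-cell flag rather than a silent continuity correction.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_out, n_ctl = a + b, c + d
    p_out = a / n_out
    p_ctl = c / n_ctl
    if a == 0 or c == 0:
        rr = np.inf if (c == 0 and a > 0) else (0.0 if a == 0 and c > 0 else np.nan)
        return EnrichmentResult(rr, np.nan, np.nan, np.nan, np.nan,
                                n_out, n_ctl, zero_cell=True)
    rr = p_out / p_ctl
    se = np.sqrt(1.0 / a - 1.0 / n_out + 1.0 / c - 1.0 / n_ctl)
    log_rr = np.log(rr)
    if se == 0:
        ci_low = ci_high = rr
        p = 1.0 if log_rr <= 0 else 0.0
    else:
        z = stats.norm.ppf(0.975)
        ci_low = float(np.exp(log_rr - z * se))
        ci_high = float(np.exp(log_rr + z * se))
        t = log_rr / se
        p = float(stats.t.sf(t, df=n_out + n_ctl - 2))
    return EnrichmentResult(float(rr), ci_low, ci_high, p, float(se),
                            n_out, n_ctl, zero_cell=False)


def enrichment_from_indicator(indicator: pd.DataFrame, outlier_mask: pd.DataFrame,
                              control_mask: pd.DataFrame) -> EnrichmentResult:
    """Build the 2x2 table from a binary variant-indicator matrix and
    aligned boolean (feature, individual) outlier/control masks."""
    ind = indicator.to_numpy(bool)
    om = outlier_mask.to_numpy(bool)
    cm = control_mask.to_numpy(bool)
    a = int((om & ind).sum())
    b = int((om & ~ind).sum())
    c = int((cm & ind).sum())
    d = int((cm & ~ind).sum())
    return relative_risk(ContingencyTable(a, b, c, d))


def compare_relative_risks(r1: EnrichmentResult, r2: EnrichmentResult):
    """Two-enrichment comparison: t = (log RR1 - log RR2) / sqrt(SE1^2+SE2^2),
    two-sided p at df = total outlier + control instances over both - 2."""
    if r1.zero_cell or r2.zero_cell or not np.isfinite(r1.se_log_rr) \
            or not np.isfinite(r2.se_log_rr):
        raise ValueError("both enrichments need defined standard errors")
    se = np.sqrt(r1.se_log_rr ** 2 + r2.se_log_rr ** 2)
    t = (np.log(r1.relative_risk) - np.log(r2.relative_risk)) / se
    df = r1.n_outlier + r1.n_control + r2.n_outlier + r2.n_control - 2
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return float(t), p


def ancestry_matched_controls(outliers, controls, pcs: pd.DataFrame) -> pd.DataFrame:
    """Pair each outlier with its nearest control in genotype-PC space.

    Euclidean distance on the PC rows; exact ties break to the
    lexicographically smaller control ID; controls may be reused. Raises if
    any listed individual lacks a PC row.
    """
    outliers = list(outliers)
    controls = sorted(set(controls), key=str)
    if not controls:
        raise ValueError("control pool is empty")
    missing = [i for i in [*outliers, *controls] if i not in pcs.index]
    if missing:
        raise ValueError(f"individuals missing PC rows: {missing}")
    C = pcs.loc[controls].to_numpy(float)
    rows = []
    for o in outliers:
        d = np.sqrt(((C - pcs.loc[o].to_numpy(float)) ** 2).sum(axis=1))
        best = int(np.argmin(d))   # argmin takes the first = smallest ID on ties
        rows.append((o, controls[best], float(d[best])))
    return pd.DataFrame(rows, columns=["outlier", "control", "distance"])
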