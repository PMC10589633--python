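"""TSV readers/writers for the pipeline's flat-file formats.

All matrices are features x individuals with a header row of individual
IDs and the feature ID in the first column. Coordinates are BED-style
0-based half-open; 1-based inputs should be converted at this boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    """Feature x individual matrix from TSV (first column = feature ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicated feature or individual IDs in {path}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    """BED-like coordinate table, indexed by the name column."""
    df = pd.read_csv(path, sep="\t", header=None, names=list(names))
    return df.set_index("name")


def read_variant_table(path) -> pd.DataFrame:
    """Rare-variant table; the carriers column is comma-separated IDs."""
    df = pd.read_csv(path, sep="\t")
    if "carriers" in df.columns:
        df["carriers"] = df["carriers"].fillna("").map(
            lambda s: [c for c in str(s).split(",") if c])
    return df


def write_variant_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "carriers" in out.columns:
        out["carriers"] = out["carriers"].map(
            lambda v: ",".join(v) if not isinstance(v, str) else v)
    out.to_csv(path, sep="\t", index=False)


def read_config(path) -> dict:
    """Flat key-value config: one `key = value` per line, '#' comments."""
    cfg = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            cfg[key.strip()] = _coerce(value.strip())
    return cfg


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def write_parameters(params, path) -> None:
    """Serialize CRF parameters to a plain-text block format."""
    with open(path, "w") as fh:
        fh.write(f"# signals: {','.join(params.signal_names)}\n")
        fh.write(f"penalty\t{params.penalty}\n")
        for k, name in enumerate(params.signal_names):
            fh.write(f"beta\t{name}\t" +
                     "\t".join(f"{v:.10g}" for v in params.beta[k]) + "\n")
        K = params.n_signals
        for k in range(K):
            for l in range(k + 1, K):
                fh.write(f"theta\t{params.signal_names[k]}\t"
                         f"{params.signal_names[l]}\t{params.theta[k, l]:.10g}\n")
        for k, name in enumerate(params.signal_names):
            for z in (0, 1):
                fh.write(f"phi\t{name}\t{z}\t" +
                         "\t".join(f"{v:.10g}" for v in params.phi[k][z]) + "\n")


def read_parameters(path):
    from .watershed.params import WatershedParameters

    penalty = 1.0
    betas, thetas, phis = {}, {}, {}
    names = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                names = line.split(":", 1)[1].strip().split(",")
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "penalty":
                penalty = float(parts[1])
            elif parts[0] == "beta":
                betas[parts[1]] = np.array([float(v) for v in parts[2:]])
            elif parts[0] == "theta":
                thetas[(parts[1], parts[2])] = float(parts[3])
            elif parts[0] == "phi":
                phis.setdefault(parts[1], {})[int(parts[2])] = np.array(
                    [float(v) for v in parts[3:]])
    K = len(names)
    beta = np.array([betas[n] for n in names])
    theta = np.zeros((K, K))
    for (a, b), v in thetas.items():
        i, j = names.index(a), names.index(b)
        theta[i, j] = theta[j, i] = v
    phi = [np.vstack([phis[n][0], phis[n][1]]) for n in names]
    return WatershedParameters(beta=beta, theta=theta, phi=phi,
                               penalty=penalty, signal_names=tuple(names))
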