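"""Synthetic-cohort simulator.

Generates cohorts with the statistical structure the pipeline assumes:

* per-instance annotation vectors G (mixture of binary and continuous
  features, an informative subset carrying true weight),
* latent regulatory states Z drawn exactly from the CRF P(z | G; beta,
  theta) by enumeration over the 2^K configurations,
* categorical outlier statuses E ~ phi_k(. | Z_k) with per-signal
  missingness,
* two-exam Z-score matrices per signal with tunable cross-exam correlation
  and injected outlier effects,
* Dirichlet-Multinomial junction-cluster counts with known concentration,
* a rare-variant table whose carrier structure includes shared-variant
  (N2) pairs.

Defaults mirror the longitudinal two-exam blood multi-omics design the
pipeline targets: four signals (expression, methylation, splicing,
protein) with cross-exam correlations 0.24 / 0.16 / 0.05 / 0.67 — the
median per-feature correlations reported for those data types.

All randomness flows from one master seed through deterministically
spawned child streams, so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .watershed.inference import crf_prior, enumerate_states
from .watershed.params import MISSING, WatershedParameters

#: signal order used throughout
SIGNALS = ("expression", "methylation", "splicing", "protein")
DEFAULT_EXAM_CORRELATION = {
    "expression": 0.24, "methylation": 0.16, "splicing": 0.05, "protein": 0.67,
}


def default_true_parameters(n_signals: int = 4, n_annotations: int = 10,
                            penalty: float = 1.0) -> WatershedParameters:
    """A realistic informative parameter set for simulation.

    Intercepts keep latent functional states rare (~10%); each signal loads
    on a small set of annotations; couplings are strongest between
    expression and methylation/splicing; emissions make observed outlier
    status informative but noisy.
    """
    rng = np.random.default_rng(12345)   # fixed: part of the default config
    beta = np.zeros((n_signals, n_annotations + 1))
    beta[:, 0] = -2.5
    n_informative = min(3, n_annotations)
    for k in range(n_signals):
        cols = (np.arange(n_informative) + k) % n_annotations
        beta[k, 1 + cols] = 2.2 + 0.2 * rng.standard_normal(n_informative)
    theta = np.zeros((n_signals, n_signals))
    for k in range(n_signals):
        for l in range(k + 1, n_signals):
            theta[k, l] = theta[l, k] = 0.3
    if n_signals >= 3:
        theta[0, 1] = theta[1, 0] = 0.8   # expression-methylation
        theta[0, 2] = theta[2, 0] = 0.8   # expression-splicing
    n_cat = [3, 3, 2, 3][:n_signals] + [3] * max(0, n_signals - 4)
    phi = []
    for c in n_cat:
        if c == 3:
            phi.append(np.array([[0.95, 0.025, 0.025],
                                 [0.30, 0.350, 0.350]]))
        else:
            phi.append(np.array([[0.96, 0.04],
                                 [0.35, 0.65]]))
    return WatershedParameters(beta=beta, theta=theta, phi=phi,
                               penalty=penalty,
                               signal_names=SIGNALS[:n_signals])


@dataclass
class SimulationConfig:
    """Cohort-generator settings; the defaults are the study conditions."""

    n_individuals: int = 200
    n_genes: int = 50
    n_signals: int = 4
    n_annotations: int = 10
    true_params: WatershedParameters | None = None
    exam_correlation: object = None     # scalar or per-signal sequence
    outlier_inject_rate: float = 0.005
    missing_rate: float = 0.10
    n2_fraction: float = 0.10
    binary_annotation_fraction: float = 0.5
    binary_annotation_rate: float = 0.25
    outlier_z_magnitude: float = 5.0
    n_clusters: int = 20
    cluster_alpha: object = None        # per-cluster alpha vectors
    junction_depth: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_genes", "n_signals", "n_annotations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.true_params is None:
            self.true_params = default_true_parameters(
                self.n_signals, self.n_annotations)
        if self.true_params.n_annotations != self.n_annotations:
            raise ValueError(
                "true_params beta dimension does not match n_annotations")
        if self.true_params.n_signals != self.n_signals:
            raise ValueError("true_params does not match n_signals")
        if self.exam_correlation is None:
            self.exam_correlation = [
                DEFAULT_EXAM_CORRELATION.get(s, 0.5)
                for s in self.true_params.signal_names
            ]
        rho = np.atleast_1d(np.asarray(self.exam_correlation, float))
        if rho.size == 1:
            rho = np.repeat(rho, self.n_signals)
        if rho.size != self.n_signals or np.any((rho < 0) | (rho > 1)):
            raise ValueError("exam_correlation must be in [0, 1] per signal")
        self.exam_correlation = rho
        for name in ("outlier_inject_rate", "missing_rate", "n2_fraction",
                     "binary_annotation_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cluster_alpha is None:
            self.cluster_alpha = [np.array([10.0, 5.0, 5.0])] * self.n_clusters
        for a in self.cluster_alpha:
            if np.any(np.asarray(a, float) <= 0):
                raise ValueError("cluster alpha entries must be positive")


@dataclass
class SimulatedCohort:
    instances: pd.DataFrame            # gene, individual, g*, e_*, z-truths
    truth: dict                        # latent states + generating params
    zscore_matrices: dict              # (signal, exam) -> DataFrame
    junction_clusters: list            # list of dicts with counts/alpha/gene
    variant_table: pd.DataFrame
    config: SimulationConfig


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_annotations(config: SimulationConfig, n: int, rng) -> np.ndarray:
    P = config.n_annotations
    n_bin = int(round(P * config.binary_annotation_fraction))
    G = np.empty((n, P))
    G[:, :n_bin] = rng.binomial(1, config.binary_annotation_rate, size=(n, n_bin))
    G[:, n_bin:] = rng.standard_normal((n, P - n_bin))
    return G


def sample_latent_states(G: np.ndarray, params: WatershedParameters,
                         rng) -> np.ndarray:
    """Draw Z ~ CRF(G) exactly: enumerate the 2^K state probabilities and
    sample a state index per instance."""
    probs = crf_prior(G, params)
    states = enumerate_states(params.n_signals).astype(int)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(G.shape[0])
    idx = (u[:, None] > cum).sum(axis=1)
    return states[idx]


def sample_outlier_status(Z: np.ndarray, params: WatershedParameters,
                          missing_rate: float, rng) -> np.ndarray:
    n, K = Z.shape
    E = np.empty((n, K), dtype=int)
    for k in range(K):
        tab = params.phi[k]
        cum = np.cumsum(tab, axis=1)
        u = rng.random(n)
        E[:, k] = (u[:, None] > cum[Z[:, k]]).sum(axis=1)
    miss = rng.random((n, K)) < missing_rate
    E[miss] = MISSING
    return E


def _median_z_from_status(E: np.ndarray, n_categories, rng,
                          magnitude: float = 3.5) -> np.ndarray:
    """Median Z-scores consistent with the categorical status: nulls inside
    the outlier threshold, outliers beyond it with the matching sign."""
    n, K = E.shape
    z = np.clip(rng.standard_normal((n, K)), -2.5, 2.5)
    for k in range(K):
        tail = np.abs(rng.standard_normal(n))
        if n_categories[k] == 2:
            z[:, k] = np.abs(z[:, k])
            out = E[:, k] == 1
            z[out, k] = magnitude + tail[out]
        else:
            under = E[:, k] == 1
            over = E[:, k] == 2
            z[under, k] = -(magnitude + tail[under])
            z[over, k] = magnitude + tail[over]
        z[E[:, k] == MISSING, k] = np.nan
    return z


def simulate_watershed_instances(config: SimulationConfig) -> SimulatedCohort:
    """Full generative pass: G -> Z ~ CRF -> E ~ phi, plus variant table,
    two-exam matrices, and junction clusters."""
    params = config.true_params
    rng_g, rng_z, rng_e, rng_zmat, rng_junc, rng_var, rng_medz = _streams(
        config.seed, 7)
    n = config.n_individuals * config.n_genes
    genes = np.repeat([f"gene{i:04d}" for i in range(config.n_genes)],
                      config.n_individuals)
    individuals = np.tile([f"ind{i:04d}" for i in range(config.n_individuals)],
                          config.n_genes)
    G = sample_annotations(config, n, rng_g)

    # N2 structure: within each gene, a fraction of individuals are paired;
    # the partner inherits the same variant set and hence the same G.
    # Because the shared rare variant is the putative cause, N2 partners
    # also share the latent regulatory state Z drawn below.
    variant_rows = []
    pair_partner = np.full(n, -1)
    per_gene_pairs = int(config.n2_fraction * config.n_individuals / 2)
    if per_gene_pairs:
        for g in range(config.n_genes):
            block = np.arange(g * config.n_individuals,
                              (g + 1) * config.n_individuals)
            chosen = rng_var.choice(block, size=2 * per_gene_pairs,
                                    replace=False)
            for a, b in zip(chosen[:per_gene_pairs], chosen[per_gene_pairs:]):
                G[b] = G[a]
                pair_partner[a], pair_partner[b] = b, a
    vid = 0
    variants = np.empty(n, dtype=object)
    for i in range(n):
        if pair_partner[i] >= 0 and pair_partner[i] < i:
            variants[i] = variants[pair_partner[i]]
            continue
        n_var = 1 + rng_var.integers(2)
        vset = tuple(f"var{vid + j:06d}" for j in range(n_var))
        vid += n_var
        variants[i] = vset
    for i in range(n):
        for v in variants[i]:
            variant_rows.append((v, genes[i], individuals[i]))
    variant_table = pd.DataFrame(variant_rows,
                                 columns=["variant", "gene", "individual"])

    Z = sample_latent_states(G, params, rng_z)
    # N2 partners carry the identical rare-variant set, so they share the
    # latent regulatory state; their observed statuses E stay independent
    # draws from phi given that shared Z.
    for a in range(n):
        b = pair_partner[a]
        if b > a:
            Z[b] = Z[a]
    E = sample_outlier_status(Z, params, config.missing_rate, rng_e)
    median_z = _median_z_from_status(E, params.n_categories, rng_medz)

    inst = pd.DataFrame({"gene": genes, "individual": individuals})
    for j in range(config.n_annotations):
        inst[f"g{j}"] = G[:, j]
    for k, name in enumerate(params.signal_names):
        inst[f"e_{name}"] = E[:, k]
        inst[f"z_{name}"] = median_z[:, k]
    inst["variants"] = list(variants)
    inst["n2_partner"] = [
        individuals[p] if p >= 0 else "" for p in pair_partner
    ]

    zmats = simulate_omics_matrices(config, rng=rng_zmat)
    clusters = simulate_junction_clusters(config, rng=rng_junc)
    truth = {
        "Z": pd.DataFrame(Z, columns=[f"z_true_{s}" for s in params.signal_names]
                          ).assign(gene=genes, individual=individuals),
        "params": params,
    }
    return SimulatedCohort(instances=inst, truth=truth, zscore_matrices=zmats,
                           junction_clusters=clusters,
                           variant_table=variant_table, config=config)


def simulate_omics_matrices(config: SimulationConfig, rng=None) -> dict:
    """Two-exam Z-score matrices per signal.

    Per feature and individual the two exams share a latent component with
    weight sqrt(rho), so the per-feature cross-exam Pearson correlation is
    rho. Injected outliers appear in both exams at the configured magnitude.
    """
    if rng is None:
        rng = _streams(config.seed, 7)[3]
    features = [f"gene{i:04d}" for i in range(config.n_genes)]
    individuals = [f"ind{i:04d}" for i in range(config.n_individuals)]
    out = {}
    for k, name in enumerate(config.true_params.signal_names):
        rho = float(config.exam_correlation[k])
        shape = (config.n_genes, config.n_individuals)
        common = rng.standard_normal(shape)
        e1 = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal(shape)
        e2 = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal(shape)
        inj = rng.random(shape) < config.outlier_inject_rate
        sign = np.where(rng.random(shape) < 0.5, -1.0, 1.0)
        mag = config.outlier_z_magnitude
        e1 = np.where(inj, sign * mag, e1)
        e2 = np.where(inj, sign * mag, e2)
        out[(name, "exam1")] = pd.DataFrame(e1, index=features, columns=individuals)
        out[(name, "exam5")] = pd.DataFrame(e2, index=features, columns=individuals)
    return out


def sample_dirichlet_multinomial(alpha, depths, rng) -> np.ndarray:
    """Draw one DM count vector per depth; rows sum to the given depths."""
    alpha = np.asarray(alpha, float)
    depths = np.asarray(depths, int)
    counts = np.zeros((len(depths), len(alpha)), dtype=int)
    pos = depths > 0
    if np.any(pos):
        p = rng.dirichlet(alpha, size=int(pos.sum()))
        counts[pos] = np.array(
            [rng.multinomial(d, pi) for d, pi in zip(depths[pos], p)]
        )
    return counts


def simulate_junction_clusters(config: SimulationConfig, rng=None) -> list:
    """Junction-cluster count matrices drawn from known-alpha DM models."""
    if rng is None:
        rng = _streams(config.seed, 7)[4]
    individuals = [f"ind{i:04d}" for i in range(config.n_individuals)]
    clusters = []
    for c, alpha in enumerate(config.cluster_alpha[:config.n_clusters]):
        alpha = np.asarray(alpha, float)
        depths = np.full(config.n_individuals, config.junction_depth, dtype=int)
        counts = sample_dirichlet_multinomial(alpha, depths, rng)
        gene = f"gene{c % config.n_genes:04d}"
        clusters.append({
            "cluster_id": f"clu{c:04d}",
            "gene": gene,
            "alpha_true": alpha,
            "counts": pd.DataFrame(
                counts, index=individuals,
                columns=[f"clu{c:04d}:j{j}" for j in range(len(alpha))],
            ),
        })
    return clusters
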