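"""Model/Results interface for the multi-omics CRF.

``Watershed`` is constructed from per-instance annotations G and categorical
outlier statuses E; ``fit()`` runs EM with exact inference and returns a
``WatershedResults`` carrying the estimates, the objective path, posterior
scoring, N2 evaluation, and a text ``summary()``.

``River`` is the single-signal special case (K = 1): identical machinery on
one outlier signal, so its posteriors coincide with a K = 1 Watershed by
construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import em as _em
from . import inference as _inf
from .gam import fit_gam, gam_predict
from .params import DEFAULT_SIGNALS, MISSING, WatershedParameters


class Watershed:
    """Latent-variable CRF linking genomic annotations to outlier signals.

    Parameters
    ----------
    annotations : (n, P) array or DataFrame
        Standardized per-instance annotation vectors G.
    outlier_status : (n, K) integer array
        Categorical outlier status E per signal; -1 marks missing.
        Directional signals use {0: none, 1: under, 2: over}; splicing
        uses {0: none, 1: outlier}.
    signal_names, n_categories : optional signal layout; defaults to the
        four-signal layout (expression, methylation, splicing, protein)
        truncated to K.
    penalty : L2 weight lambda on beta and theta.
    """

    def __init__(self, annotations, outlier_status, signal_names=None,
                 n_categories=None, penalty: float = 1.0):
        if isinstance(annotations, pd.DataFrame):
            self.annotation_names = list(annotations.columns)
            annotations = annotations.to_numpy(float)
        else:
            annotations = np.asarray(annotations, float)
            self.annotation_names = [f"g{i}" for i in range(annotations.shape[1])]
        E = np.asarray(outlier_status, int)
        if E.ndim != 2 or E.shape[0] != annotations.shape[0]:
            raise ValueError("annotations and outlier_status must align on rows")
        K = E.shape[1]
        if signal_names is None:
            signal_names = list(DEFAULT_SIGNALS)[:K]
            if len(signal_names) < K:
                signal_names = [f"signal_{k}" for k in range(K)]
        if n_categories is None:
            n_categories = [DEFAULT_SIGNALS.get(s, 3) for s in signal_names]
        for k in range(K):
            col = E[:, k]
            if np.any((col != MISSING) & ((col < 0) | (col >= n_categories[k]))):
                raise ValueError(f"invalid category code in signal {signal_names[k]}")
        self.G = annotations
        self.E = E
        self.signal_names = tuple(signal_names)
        self.n_categories = tuple(n_categories)
        self.penalty = float(penalty)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, annotation_cols, signal_cols,
                       n_categories=None, penalty: float = 1.0) -> "Watershed":
        """Build from a wide per-instance table (one row per gene-individual)."""
        return cls(df[list(annotation_cols)],
                   df[list(signal_cols)].fillna(MISSING).to_numpy(int),
                   signal_names=list(signal_cols), n_categories=n_categories,
                   penalty=penalty)

    @property
    def n_signals(self) -> int:
        return self.E.shape[1]

    def initial_parameters(self) -> WatershedParameters:
        """Deterministic warm start (GAM betas, theta = 0, empirical phi)."""
        return _em.initialize_parameters(
            self.G, self.E, self.penalty, self.n_categories,
            signal_names=self.signal_names,
        )

    def loglike(self, params: WatershedParameters) -> float:
        """Penalized marginal log-likelihood at the given parameters."""
        return _inf.marginal_log_likelihood(self.G, self.E, params)

    def fit(self, start_params: WatershedParameters | None = None,
            max_iter: int = 300, tol: float = 1e-6) -> "WatershedResults":
        init = start_params if start_params is not None else self.initial_parameters()
        params, history = _em.train_em(self.G, self.E, init,
                                       max_iter=max_iter, tol=tol)
        return WatershedResults(self, params, history)

    def fit_gam(self) -> np.ndarray:
        """Annotation-only baseline: per-signal penalized logistic fits.

        Labels collapse all outlier categories to a single positive class.
        Returns (K, P+1) coefficients.
        """
        coefs = np.zeros((self.n_signals, self.G.shape[1] + 1))
        for k in range(self.n_signals):
            obs = self.E[:, k] != MISSING
            y = (self.E[obs, k] > 0).astype(int)
            coefs[k] = fit_gam(self.G[obs], y, penalty=self.penalty)
        return coefs


class WatershedResults:
    """Fitted CRF: parameter estimates plus scoring and evaluation."""

    def __init__(self, model: Watershed, params: WatershedParameters,
                 history: "_em.EMHistory"):
        self.model = model
        self.params = params
        self.history = history

    @property
    def converged(self) -> bool:
        return self.history.converged

    @property
    def objective_path(self) -> np.ndarray:
        return np.asarray(self.history.objective)

    def posterior(self, G=None, E=None) -> np.ndarray:
        """Marginal posteriors P(Z_k = 1 | G, E) for all K signals.

        Defaults to the training instances. E entries of -1 are treated as
        missing and marginalized; posteriors are still returned for every
        signal.
        """
        if G is None:
            G = self.model.G
        if E is None:
            E = self.model.E if G is self.model.G else np.full(
                (np.atleast_2d(G).shape[0], self.params.n_signals), MISSING)
        return _inf.joint_posterior(G, E, self.params)

    def prior(self, G=None) -> np.ndarray:
        if G is None:
            G = self.model.G
        return _inf.prior_marginals(G, self.params)

    def loglike(self) -> float:
        return self.model.loglike(self.params)

    def evaluate_n2(self, pairs, G_lookup, E_lookup, gam_coefs=None, **kw):
        from .evaluate import evaluate_n2
        return evaluate_n2(pairs, G_lookup, E_lookup, self.params,
                           gam_coefs=gam_coefs, **kw)

    def summary(self) -> str:
        p = self.params
        lines = ["Multi-omics Watershed CRF (exact inference, EM)"]
        lines.append(f"  instances: {self.model.G.shape[0]}  "
                     f"annotations: {self.model.G.shape[1]}  "
                     f"signals: {p.n_signals}  penalty: {p.penalty}")
        lines.append(f"  EM iterations: {self.history.n_iter}  "
                     f"converged: {self.history.converged}  "
                     f"objective: {self.objective_path[-1]:.4f}")
        lines.append("")
        lines.append("Pairwise latent couplings theta (symmetric):")
        names = list(p.signal_names)
        header = "            " + "".join(f"{n[:10]:>12}" for n in names)
        lines.append(header)
        for k, n in enumerate(names):
            row = "".join(f"{p.theta[k, l]:12.4f}" for l in range(p.n_signals))
            lines.append(f"{n[:10]:>12}{row}")
        lines.append("")
        lines.append("Top annotation weights |beta| per signal:")
        ann = self.model.annotation_names
        for k, n in enumerate(names):
            w = p.beta[k, 1:]
            order = np.argsort(-np.abs(w))[:5]
            tops = ", ".join(f"{ann[i]}={w[i]:+.3f}" for i in order)
            lines.append(f"  {n}: intercept={p.beta[k, 0]:+.3f}; {tops}")
        lines.append("")
        lines.append("Emission tables phi (rows: Z=0, Z=1):")
        for k, n in enumerate(names):
            for z in (0, 1):
                vals = " ".join(f"{v:.3f}" for v in p.phi[k][z])
                lines.append(f"  {n} Z={z}: [{vals}]")
        return "\n".join(lines)


class River(Watershed):
    """Single-signal special case of the CRF (K = 1, no theta)."""

    def __init__(self, annotations, outlier_status, signal_name="expression",
                 n_categories: int = 3, penalty: float = 1.0):
        E = np.asarray(outlier_status, int)
        if E.ndim == 1:
            E = E[:, None]
        if E.shape[1] != 1:
            raise ValueError("River models exactly one outlier signal")
        super().__init__(annotations, E, signal_names=[signal_name],
                         n_categories=[n_categories], penalty=penalty)


def fit_river(annotations, outlier_status, signal_name="expression",
              n_categories: int = 3, penalty: float = 1.0,
              **fit_kw) -> WatershedResults:
    """Convenience: construct and fit a single-signal model."""
    return River(annotations, outlier_status, signal_name=signal_name,
                 n_categories=n_categories, penalty=penalty).fit(**fit_kw)
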