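"""Parameter containers for the multi-omics latent-variable CRF.

The model has K omic signals. Each signal k carries

* singleton weights ``beta[k]`` = (intercept, w_1 .. w_P) linking the
  standardized annotation vector G to the latent regulatory state Z_k,
* pairwise weights ``theta[k, l]`` coupling latent states of signals k and l,
* an emission table ``phi[k]`` of shape (2, C_k): row z gives
  P(E_k = category | Z_k = z) over the C_k observed outlier categories.

Directional signals (expression, methylation, protein) use three categories
coded 0 = none, 1 = under, 2 = over; splicing uses two categories coded
0 = none, 1 = outlier. Missing observations are coded -1 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

#: default signal layout: name -> number of observed outlier categories
DEFAULT_SIGNALS = {
    "expression": 3,
    "methylation": 3,
    "splicing": 2,
    "protein": 3,
}


@dataclass
class WatershedParameters:
    """Full parameter set (beta, theta, phi, L2 penalty) of the CRF."""

    beta: np.ndarray            # (K, P+1); column 0 is the intercept
    theta: np.ndarray           # (K, K) symmetric, zero diagonal
    phi: list                   # K arrays, each (2, C_k), rows sum to 1
    penalty: float = 1.0        # lambda of the L2 penalty on beta and theta
    signal_names: tuple = field(default_factory=lambda: tuple(DEFAULT_SIGNALS))

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi = [np.asarray(p, dtype=float) for p in self.phi]
        K = self.beta.shape[0]
        if self.theta.shape != (K, K):
            raise ValueError(
                f"theta must be ({K}, {K}) to match beta, got {self.theta.shape}"
            )
        if not np.allclose(self.theta, self.theta.T):
            raise ValueError("theta must be symmetric")
        if np.any(np.diag(self.theta) != 0):
            raise ValueError("theta must have a zero diagonal")
        if len(self.phi) != K:
            raise ValueError("phi must have one table per signal")
        for k, p in enumerate(self.phi):
            if p.ndim != 2 or p.shape[0] != 2:
                raise ValueError(f"phi[{k}] must have shape (2, C_k)")
            if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0):
                raise ValueError(f"phi[{k}] rows must be probability vectors")
        if len(self.signal_names) != K:
            self.signal_names = tuple(f"signal_{k}" for k in range(K))

    @property
    def n_signals(self) -> int:
        return self.beta.shape[0]

    @property
    def n_annotations(self) -> int:
        return self.beta.shape[1] - 1

    @property
    def n_categories(self) -> tuple:
        return tuple(p.shape[1] for p in self.phi)

    def copy(self) -> "WatershedParameters":
        return WatershedParameters(
            beta=self.beta.copy(),
            theta=self.theta.copy(),
            phi=[p.copy() for p in self.phi],
            penalty=self.penalty,
            signal_names=self.signal_names,
        )


def uninformative_parameters(
    n_signals: int,
    n_annotations: int,
    n_categories=None,
    penalty: float = 1.0,
    signal_names=None,
) -> WatershedParameters:
    """Zero weights and uniform emissions: a maximally agnostic model."""
    if n_categories is None:
        n_categories = list(DEFAULT_SIGNALS.values())[:n_signals]
        if len(n_categories) < n_signals:
            n_categories = [3] * n_signals
    phi = [np.full((2, c), 1.0 / c) for c in n_categories]
    if signal_names is None:
        signal_names = list(DEFAULT_SIGNALS)[:n_signals]
        if len(signal_names) < n_signals:
            signal_names = [f"signal_{k}" for k in range(n_signals)]
    return WatershedParameters(
        beta=np.zeros((n_signals, n_annotations + 1)),
        theta=np.zeros((n_signals, n_signals)),
        phi=phi,
        penalty=penalty,
        signal_names=tuple(signal_names),
    )
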