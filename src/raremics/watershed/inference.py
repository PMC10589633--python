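"""Exact inference for the latent-variable CRF over K binary signals.

With K = 4 the latent space has 2^K = 16 configurations, so every quantity
(the normalizer, marginals, posteriors, the marginal likelihood) is computed
by explicit enumeration — no approximation anywhere.

Model:
    P(z | G)        prop. exp( sum_k z_k (beta_k0 + beta_k . G)
                               + sum_{k<l} theta_kl z_k z_l )
    P(E | z)        = prod_{k observed} phi_k(E_k | z_k)
    P(z | G, E)     prop. P(z | G) P(E | z)

Missing E_k (coded -1) contribute no evidence and are marginalized away by
construction.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .params import MISSING, WatershedParameters


def enumerate_states(n_signals: int) -> np.ndarray:
    """All 2^K binary latent configurations, shape (2^K, K).

    State s has bit k equal to ``(s >> k) & 1`` so state 0 is all-zero.
    """
    s = np.arange(2 ** n_signals)
    return ((s[:, None] >> np.arange(n_signals)[None, :]) & 1).astype(float)


def _pair_index(n_signals: int):
    """Upper-triangle (k, l) index pairs, k < l."""
    iu = np.triu_indices(n_signals, k=1)
    return iu


def _as_2d(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    return G[None, :] if G.ndim == 1 else G


def crf_log_prior(G: np.ndarray, params: WatershedParameters) -> np.ndarray:
    """Log P(z | G) for every latent configuration; shape (n, 2^K)."""
    G = _as_2d(G)
    K = params.n_signals
    states = enumerate_states(K)
    X = np.column_stack([np.ones(G.shape[0]), G])     # (n, P+1)
    eta = X @ params.beta.T                           # (n, K) singleton scores
    iu = _pair_index(K)
    theta_vec = params.theta[iu]                      # (n_pairs,)
    pair_states = states[:, iu[0]] * states[:, iu[1]]  # (2^K, n_pairs)
    scores = eta @ states.T + pair_states @ theta_vec  # (n, 2^K)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite CRF potential; check G and parameters")
    return scores - logsumexp(scores, axis=1, keepdims=True)


def crf_prior(G: np.ndarray, params: WatershedParameters) -> np.ndarray:
    """P(z | G) over all 2^K configurations; rows sum to one."""
    return np.exp(crf_log_prior(G, params))


def emission_log_likelihood(E: np.ndarray, params: WatershedParameters) -> np.ndarray:
    """Log P(E_obs | z) for every configuration; shape (n, 2^K).

    E is (n, K) integer-coded with -1 for missing; missing entries add zero
    log-likelihood under every z (they are marginalized).
    """
    E = np.atleast_2d(np.asarray(E))
    n = E.shape[0]
    K = params.n_signals
    states = enumerate_states(K).astype(int)
    out = np.zeros((n, states.shape[0]))
    for k in range(K):
        e = E[:, k]
        obs = e != MISSING
        if not np.any(obs):
            continue
        tab = params.phi[k]
        if np.any((e[obs] < 0) | (e[obs] >= tab.shape[1])):
            raise ValueError(f"outlier category out of range for signal {k}")
        with np.errstate(divide="ignore"):
            log_tab = np.log(tab)                      # (2, C_k)
        contrib = log_tab[:, e[obs]].T                 # (n_obs, 2)
        if np.any(np.isneginf(contrib)):
            raise ValueError(
                f"phi[{k}] has zero mass on an observed category; "
                "train with pseudocounts"
            )
        out[obs] += contrib[:, states[:, k]]
    return out


def joint_log_posterior(G, E, params: WatershedParameters) -> np.ndarray:
    """Log P(z | G, E) over all 2^K configurations; shape (n, 2^K)."""
    lp = crf_log_prior(G, params) + emission_log_likelihood(E, params)
    return lp - logsumexp(lp, axis=1, keepdims=True)


def joint_posterior(G, E, params: WatershedParameters) -> np.ndarray:
    """Marginal posteriors P(Z_k = 1 | G, E) for all K signals; shape (n, K).

    Computed for every signal whether or not its E is observed.
    """
    post = np.exp(joint_log_posterior(G, E, params))
    states = enumerate_states(params.n_signals)
    return post @ states


def prior_marginals(G, params: WatershedParameters) -> np.ndarray:
    """Marginal priors P(Z_k = 1 | G); shape (n, K)."""
    states = enumerate_states(params.n_signals)
    return crf_prior(G, params) @ states


def marginal_log_likelihood(G, E, params: WatershedParameters) -> float:
    """Penalized marginal log-likelihood of the observed outlier statuses.

    sum_n log sum_z P(E_obs^n | z) P(z | G^n)  -  lambda (||beta||^2 + ||theta||^2)

    theta is counted once per unordered pair. Instances whose E is entirely
    missing contribute zero (their marginal likelihood is one).
    """
    lp = crf_log_prior(G, params) + emission_log_likelihood(E, params)
    data_term = float(np.sum(logsumexp(lp, axis=1)))
    iu = _pair_index(params.n_signals)
    pen = params.penalty * (
        float(np.sum(params.beta ** 2)) + float(np.sum(params.theta[iu] ** 2))
    )
    return data_term - pen
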