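"""EM training for the latent-variable CRF.

E-step: exact posteriors q(z) per instance by enumeration over 2^K states.
M-step:
  * emission tables phi via posterior-weighted category counts with a
    Dirichlet pseudocount of 1 per category (MAP under Dirichlet(2)),
  * (beta, theta) by maximizing the expected CRF log-likelihood with exact
    model expectations, L2 penalty lambda, run to convergence with L-BFGS.

The monitored objective is the penalized marginal log-likelihood plus the
Dirichlet log-prior on phi; MAP-EM guarantees it never decreases, and a
decrease beyond numerical tolerance raises (it would indicate an inference
bug, not a modeling problem).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .gam import fit_gam
from .inference import (
    _pair_index,
    crf_log_prior,
    emission_log_likelihood,
    enumerate_states,
    marginal_log_likelihood,
)
from .params import MISSING, WatershedParameters


@dataclass
class EMHistory:
    objective: list
    converged: bool
    n_iter: int


def _phi_log_prior(params: WatershedParameters) -> float:
    # Dirichlet(2) log-density kernel, matching pseudocount-1 MAP updates
    return float(sum(np.sum(np.log(p)) for p in params.phi))


def _expected_stats(q: np.ndarray, K: int):
    states = enumerate_states(K)
    iu = _pair_index(K)
    pair_states = states[:, iu[0]] * states[:, iu[1]]
    return q @ states, q @ pair_states      # (n, K), (n, n_pairs)


def _optimize_crf_weights(X, q_marg, q_pair, params: WatershedParameters,
                          gtol: float = 1e-8) -> WatershedParameters:
    """M-step for (beta, theta): full maximization of the expected
    complete-data CRF log-likelihood minus the L2 penalty."""
    K = params.n_signals
    P1 = params.beta.shape[1]
    iu = _pair_index(K)
    n_pairs = len(iu[0])
    states = enumerate_states(K)
    pair_states = states[:, iu[0]] * states[:, iu[1]]
    lam = params.penalty

    def unpack(x):
        beta = x[: K * P1].reshape(K, P1)
        theta_vec = x[K * P1:]
        return beta, theta_vec

    def negobj(x):
        beta, theta_vec = unpack(x)
        eta = X @ beta.T
        scores = eta @ states.T + pair_states @ theta_vec
        logZ = logsumexp(scores, axis=1)
        f = (np.sum(q_marg * eta) + q_pair.sum(axis=0) @ theta_vec
             - np.sum(logZ))
        f -= lam * (np.sum(beta ** 2) + np.sum(theta_vec ** 2))
        # model expectations for the gradient
        p = np.exp(scores - logZ[:, None])
        p_marg = p @ states
        p_pair = p @ pair_states
        g_beta = (q_marg - p_marg).T @ X - 2.0 * lam * beta
        g_theta = (q_pair - p_pair).sum(axis=0) - 2.0 * lam * theta_vec
        return -f, -np.concatenate([g_beta.ravel(), g_theta])

    x0 = np.concatenate([params.beta.ravel(), params.theta[iu]])
    res = minimize(negobj, x0, jac=True, method="L-BFGS-B",
                   options={"gtol": gtol, "maxiter": 500})
    # L-BFGS starts at the current parameters, so the returned point can
    # only improve (or match) the expected objective
    if negobj(res.x)[0] > negobj(x0)[0] + 1e-10:
        res_x = x0
    else:
        res_x = res.x
    beta, theta_vec = unpack(res_x)
    theta = np.zeros((K, K))
    theta[iu] = theta_vec
    theta = theta + theta.T
    out = params.copy()
    out.beta, out.theta = beta, theta
    return out


def _update_phi(E, q_marg, params: WatershedParameters) -> WatershedParameters:
    out = params.copy()
    for k in range(params.n_signals):
        e = E[:, k]
        obs = e != MISSING
        C = params.phi[k].shape[1]
        counts = np.ones((2, C))      # pseudocount 1 per category
        if np.any(obs):
            w1 = q_marg[obs, k]
            eo = e[obs]
            for c in range(C):
                sel = eo == c
                counts[1, c] += w1[sel].sum()
                counts[0, c] += (1.0 - w1[sel]).sum()
        out.phi[k] = counts / counts.sum(axis=1, keepdims=True)
    return out


def initialize_parameters(G, E, penalty: float, n_categories,
                          signal_names=None) -> WatershedParameters:
    """Deterministic warm start: per-signal GAM betas, theta = 0, phi from
    label-conditional category frequencies with pseudocount 1."""
    G = np.asarray(G, float)
    E = np.asarray(E)
    K = E.shape[1]
    P = G.shape[1]
    beta = np.zeros((K, P + 1))
    phi = []
    for k in range(K):
        e = E[:, k]
        obs = e != MISSING
        y = (e[obs] > 0).astype(int)     # any outlier category vs none
        if y.size and 0 < y.sum() < y.size:
            coef = fit_gam(G[obs], y, penalty=penalty)
            beta[k] = coef
        C = n_categories[k]
        counts = np.ones((2, C))
        if y.size:
            eo = e[obs]
            for c in range(C):
                counts[1, c] += np.sum((eo == c) & (y == 1))
                counts[0, c] += np.sum((eo == c) & (y == 0))
        phi.append(counts / counts.sum(axis=1, keepdims=True))
    return WatershedParameters(beta=beta, theta=np.zeros((K, K)), phi=phi,
                               penalty=penalty,
                               signal_names=signal_names or ())


def train_em(G, E, init: WatershedParameters, max_iter: int = 300,
             tol: float = 1e-6) -> tuple[WatershedParameters, EMHistory]:
    """Run EM to convergence; returns fitted parameters and the objective path.

    Stops when the relative objective change drops below ``tol`` or after
    ``max_iter`` iterations. Raises if the objective decreases beyond
    numerical tolerance.
    """
    G = np.asarray(G, float)
    E = np.asarray(E)
    params = init.copy()
    history = []
    prev = marginal_log_likelihood(G, E, params) + _phi_log_prior(params)
    history.append(prev)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: exact state posteriors
        lp = crf_log_prior(G, params) + emission_log_likelihood(E, params)
        q = np.exp(lp - logsumexp(lp, axis=1, keepdims=True))
        q_marg, q_pair = _expected_stats(q, params.n_signals)
        # M-step
        params = _update_phi(E, q_marg, params)
        X = np.column_stack([np.ones(G.shape[0]), G])
        params = _optimize_crf_weights(X, q_marg, q_pair, params)
        obj = marginal_log_likelihood(G, E, params) + _phi_log_prior(params)
        if obj < prev - 1e-8 * (1.0 + abs(prev)):
            raise RuntimeError(
                f"EM objective decreased at iteration {it}: {prev} -> {obj}"
            )
        history.append(obj)
        if abs(obj - prev) <= tol * (1.0 + abs(prev)):
            converged = True
            prev = obj
            break
        prev = obj
    return params, EMHistory(objective=history, converged=converged, n_iter=it)
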