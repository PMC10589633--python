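"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain Python loops over explicitly enumerated
configurations, deliberately sharing no code with the package's vectorized
inference paths.
"""

import itertools

import numpy as np


def brute_state_logweights(G, E, beta, theta, phi):
    """Unnormalized log-weights of every latent configuration for one
    instance, enumerated with itertools."""
    K = beta.shape[0]
    out = []
    for z in itertools.product([0, 1], repeat=K):
        s = 0.0
        for k in range(K):
            if z[k]:
                s += beta[k, 0] + float(np.dot(beta[k, 1:], G))
        for k in range(K):
            for l in range(k + 1, K):
                if z[k] and z[l]:
                    s += theta[k, l]
        for k in range(K):
            if E[k] != -1:
                s += np.log(phi[k][z[k], E[k]])
        out.append((z, s))
    return out


def brute_posterior_marginals(G, E, beta, theta, phi):
    """P(Z_k = 1 | G, E) per signal by direct enumeration."""
    K = beta.shape[0]
    weights = brute_state_logweights(G, E, beta, theta, phi)
    m = max(s for _, s in weights)
    num = np.zeros(K)
    den = 0.0
    for z, s in weights:
        w = np.exp(s - m)
        den += w
        for k in range(K):
            if z[k]:
                num[k] += w
    return num / den


def brute_marginal_loglik(G_rows, E_rows, beta, theta, phi, lam):
    """Penalized marginal log-likelihood by enumerating prior and emission
    sums separately per instance."""
    total = 0.0
    K = beta.shape[0]
    for G, E in zip(G_rows, E_rows):
        # log normalizer of the prior (no emissions)
        prior_w = brute_state_logweights(G, [-1] * K, beta, theta, phi)
        m0 = max(s for _, s in prior_w)
        logZ = m0 + np.log(sum(np.exp(s - m0) for _, s in prior_w))
        full_w = brute_state_logweights(G, E, beta, theta, phi)
        m1 = max(s for _, s in full_w)
        logS = m1 + np.log(sum(np.exp(s - m1) for _, s in full_w))
        total += logS - logZ
    pen = lam * (float(np.sum(np.asarray(beta) ** 2))
                 + sum(theta[k, l] ** 2
                       for k in range(K) for l in range(k + 1, K)))
    return total - pen


def brute_crf_pair_correlation(beta0, theta, k1, k2):
    """Pearson correlation of (Z_k1, Z_k2) under a CRF with constant
    singleton potentials beta0 (length K) and coupling matrix theta,
    computed by full enumeration."""
    K = len(beta0)
    ws = []
    for z in itertools.product([0, 1], repeat=K):
        s = sum(beta0[k] * z[k] for k in range(K))
        s += sum(theta[k, l] * z[k] * z[l]
                 for k in range(K) for l in range(k + 1, K))
        ws.append((z, np.exp(s)))
    tot = sum(w for _, w in ws)
    e1 = sum(w * z[k1] for z, w in ws) / tot
    e2 = sum(w * z[k2] for z, w in ws) / tot
    e12 = sum(w * z[k1] * z[k2] for z, w in ws) / tot
    cov = e12 - e1 * e2
    return cov / np.sqrt(e1 * (1 - e1) * e2 * (1 - e2))


def penalized_logistic_oracle(X, y, lam):
    """L2-penalized logistic regression solved with a generic optimizer
    (Nelder-free BFGS on the exact objective), intercept unpenalized."""
    from scipy.optimize import minimize
    from scipy.special import expit

    X1 = np.column_stack([np.ones(len(y)), X])

    def negll(w):
        eta = X1 @ w
        # log(1 + exp(-y'*eta)) with y' in {-1, +1}
        ypm = 2 * y - 1
        val = np.sum(np.logaddexp(0.0, -ypm * eta)) + lam * np.sum(w[1:] ** 2)
        grad = X1.T @ (expit(eta) - y)
        grad[1:] += 2 * lam * w[1:]
        return val, grad

    res = minimize(negll, np.zeros(X1.shape[1]), jac=True, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    return res.x, res.fun
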