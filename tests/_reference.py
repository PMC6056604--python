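"""Independently coded two-level Poisson sampler used as an MCMC oracle.

Deliberately written without reference to the package's kernel: dense group
indexing instead of sparse weights, full log-likelihood recomputation on
every proposal, numpy Generator RNG, and its own adaptation rule.  It
targets the standard nested model

    Y_i ~ Poisson(t_i exp(x_i' beta + u_{g(i)})),  u_j ~ N(0, s2),

which a multiple-membership sampler must match when every weight row is a
unit vector.
"""

import numpy as np
from scipy.special import gammaln  # noqa: F401  (kept for deviance checks)


def fit_two_level(y, log_t, X, groups, n_groups, *, burnin=1000, iters=4000,
                  seed=0, beta_prior_var=1e6, ig_shape=0.001, ig_scale=0.001):
    """Random-walk Metropolis within Gibbs for the nested Poisson GLMM.

    Returns dict with 'beta' (S x P), 'u' (S x J), 'sigma2' (S,).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    n, P = X.shape
    J = n_groups

    beta = np.zeros(P)
    u = np.zeros(J)
    s2 = 0.5

    def loglik(beta, u):
        eta = log_t + X @ beta + u[groups]
        return float(np.sum(y * eta - np.exp(eta)))

    ll = loglik(beta, u)
    step_b = np.full(P, 0.2)
    step_u = np.full(J, 0.5)
    acc_b = np.zeros(P)
    acc_u = np.zeros(J)

    S = iters
    out_b = np.empty((S, P))
    out_u = np.empty((S, J))
    out_s = np.empty(S)

    for it in range(burnin + iters):
        for p in range(P):
            prop = beta.copy()
            prop[p] += step_b[p] * rng.standard_normal()
            ll_new = loglik(prop, u)
            lp = (beta[p] ** 2 - prop[p] ** 2) / (2 * beta_prior_var)
            if np.log(rng.random()) < ll_new - ll + lp:
                beta, ll = prop, ll_new
                acc_b[p] += 1
        for j in range(J):
            prop_u = u.copy()
            prop_u[j] += step_u[j] * rng.standard_normal()
            ll_new = loglik(beta, prop_u)
            lp = (u[j] ** 2 - prop_u[j] ** 2) / (2 * s2)
            if np.log(rng.random()) < ll_new - ll + lp:
                u, ll = prop_u, ll_new
                acc_u[j] += 1
        s2 = 1.0 / rng.gamma(ig_shape + J / 2.0,
                             1.0 / (ig_scale + 0.5 * float(u @ u)))
        if it < burnin and (it + 1) % 100 == 0:
            # crude Robbins-Monro-ish retuning toward ~40% acceptance
            rb = acc_b / 100.0
            ru = acc_u / 100.0
            step_b *= np.where(rb > 0.4, 1.3, 0.7)
            step_u *= np.where(ru > 0.4, 1.3, 0.7)
            acc_b[:] = 0
            acc_u[:] = 0
        elif it == burnin - 1:
            acc_b[:] = 0
            acc_u[:] = 0
        if it >= burnin:
            k = it - burnin
            out_b[k] = beta
            out_u[k] = u
            out_s[k] = s2

    return {"beta": out_b, "u": out_u, "sigma2": out_s}
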