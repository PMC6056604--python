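"""Numba kernel for the multiple-membership Poisson sampler.

Metropolis-within-Gibbs: adaptive scalar random-walk Metropolis for every
fixed effect and every random effect (the Poisson likelihood is
non-conjugate), conjugate Gibbs draws for each variance component.  The
linear predictor, its exponential and the log-likelihood are maintained
incrementally so each scalar update touches only the rows carrying weight on
that parameter.  Adaptation targets ~44% acceptance and is frozen at the end
of burn-in.
"""

import numpy as np
from numba import njit

TARGET_ACCEPT = 0.44


@njit(cache=True)
def _log_accept_ratio(y, w, rows, eta, mu, delta):
    """Likelihood log-ratio for adding delta*w on the given rows."""
    dll = 0.0
    for k in range(rows.shape[0]):
        i = rows[k]
        new_eta = eta[i] + delta * w[k]
        dll += y[i] * delta * w[k] - (np.exp(new_eta) - mu[i])
    return dll


@njit(cache=True)
def _apply(w, rows, eta, mu, delta):
    for k in range(rows.shape[0]):
        i = rows[k]
        eta[i] += delta * w[k]
        mu[i] = np.exp(eta[i])


@njit(cache=True)
def run_chain(
    seed,
    y,              # (n,) float64 counts
    X,              # (n, P) fixed-effect design
    eta0,           # (n,) initial linear predictor incl. offset
    beta_init,      # (P,)
    beta_prior_var, # scalar
    n_units,        # (C,) units per classification
    unit_class,     # (G,) classification index of each unit, G = sum(n_units)
    unit_indptr,    # (G+1,) CSC-style pointers into unit_rows/unit_w
    unit_rows,
    unit_w,
    sig_a, sig_b,   # inverse-gamma prior shape/scale
    fixed_var,      # (C,) fixed variance value, or nan if sampled
    burnin, iters, thin, adapt_interval,
):
    np.random.seed(seed)
    n = y.shape[0]
    P = X.shape[1]
    C = n_units.shape[0]
    G = unit_class.shape[0]

    beta = beta_init.copy()
    u = np.zeros(G)
    sigma2 = np.empty(C)
    for c in range(C):
        sigma2[c] = 0.1 if np.isnan(fixed_var[c]) else fixed_var[c]

    eta = eta0.copy()
    mu = np.exp(eta)
    ll = 0.0
    for i in range(n):
        ll += y[i] * eta[i] - mu[i]

    sd_beta = np.full(P, 0.1)
    sd_u = np.full(G, 0.5)
    acc_beta = np.zeros(P)
    acc_u = np.zeros(G)
    batch_beta = np.zeros(P)
    batch_u = np.zeros(G)

    S = iters // thin
    beta_chain = np.empty((S, P))
    u_chain = np.empty((S, G))
    sig_chain = np.empty((S, C))
    dev_chain = np.empty(S)

    n_batches = 0
    s_out = 0
    for it in range(burnin + iters):
        in_burnin = it < burnin

        for p in range(P):
            delta = sd_beta[p] * np.random.normal()
            new_b = beta[p] + delta
            dlp = -(new_b * new_b - beta[p] * beta[p]) / (2.0 * beta_prior_var)
            dll = 0.0
            col = X[:, p]
            for i in range(n):
                new_eta = eta[i] + delta * col[i]
                dll += y[i] * delta * col[i] - (np.exp(new_eta) - mu[i])
            if np.log(np.random.random()) < dll + dlp:
                beta[p] = new_b
                for i in range(n):
                    eta[i] += delta * col[i]
                    mu[i] = np.exp(eta[i])
                ll += dll
                if in_burnin:
                    batch_beta[p] += 1.0
                else:
                    acc_beta[p] += 1.0

        for g in range(G):
            c = unit_class[g]
            if sigma2[c] <= 0.0:
                continue
            lo, hi = unit_indptr[g], unit_indptr[g + 1]
            rows = unit_rows[lo:hi]
            w = unit_w[lo:hi]
            delta = sd_u[g] * np.random.normal()
            new_u = u[g] + delta
            dll = _log_accept_ratio(y, w, rows, eta, mu, delta)
            dlp = -(new_u * new_u - u[g] * u[g]) / (2.0 * sigma2[c])
            if np.log(np.random.random()) < dll + dlp:
                u[g] = new_u
                _apply(w, rows, eta, mu, delta)
                ll += dll
                if in_burnin:
                    batch_u[g] += 1.0
                else:
                    acc_u[g] += 1.0

        for c in range(C):
            if not np.isnan(fixed_var[c]):
                continue
            ssq = 0.0
            J = 0
            for g in range(G):
                if unit_class[g] == c:
                    ssq += u[g] * u[g]
                    J += 1
            shape = sig_a + 0.5 * J
            rate = sig_b + 0.5 * ssq
            sigma2[c] = 1.0 / np.random.gamma(shape, 1.0 / rate)

        if in_burnin and (it + 1) % adapt_interval == 0:
            n_batches += 1
            step = min(0.1, 1.0 / np.sqrt(n_batches))
            for p in range(P):
                if batch_beta[p] / adapt_interval > TARGET_ACCEPT:
                    sd_beta[p] *= np.exp(step)
                else:
                    sd_beta[p] *= np.exp(-step)
                batch_beta[p] = 0.0
            for g in range(G):
                if batch_u[g] / adapt_interval > TARGET_ACCEPT:
                    sd_u[g] *= np.exp(step)
                else:
                    sd_u[g] *= np.exp(-step)
                batch_u[g] = 0.0

        if not in_burnin and (it - burnin + 1) % thin == 0:
            beta_chain[s_out] = beta
            u_chain[s_out] = u
            sig_chain[s_out] = sigma2
            dev_chain[s_out] = -2.0 * ll
            s_out += 1

    acc_beta /= iters
    acc_u /= iters
    return beta_chain, u_chain, sig_chain, dev_chain, acc_beta, acc_u, sd_beta, sd_u
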