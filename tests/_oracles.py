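"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's samplers and likelihood plumbing:
posterior quantities are computed by dense-grid quadrature over the joint
prior, model by model, so they can certify the MCMC implementation on tiny
fixtures.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def bernoulli_expanded_loglik(y, n, p):
    """Binomial log-likelihood computed trial by trial (no shortcut)."""
    total = 0.0
    for yi, ni, pi in zip(y, n, p):
        trials = [1] * int(yi) + [0] * int(ni - yi)
        for t in trials:
            total += np.log(pi if t else 1.0 - pi)
    return total


def _loglik_grid(y, n, eta):
    """Binomial log-likelihood (with coefficient) summed over visits.

    ``eta`` has one trailing axis per visit already applied; here we expect
    an array of shape (..., n_visits).
    """
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    const = np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1))
    return const + np.sum(y * eta - n * np.logaddexp(0.0, eta), axis=-1)


def quadrature_selection_posterior(y, n, X, sigma_beta_upper=2.0,
                                   intercept_sd=10.0, n_alpha=101,
                                   n_t=81, n_s=48):
    """Exact-by-quadrature posterior for the selection model, J in {1, 2}.

    Model: logit(p_i) = alpha + sum_j gamma_j beta_j x_ij with
    alpha ~ N(0, intercept_sd^2), gamma_j ~ Bernoulli(1/2),
    beta_j ~ N(0, sigma_beta^2) shared, sigma_beta ~ U(0, upper).
    No random effects.  Returns inclusion probabilities and posterior
    means of gamma_j * beta_j.

    The beta integrals substitute beta = sigma * t so the marginal prior's
    log-singularity at beta = 0 never meets the grid: for each sigma the
    inner integral is over a standard-normal-weighted smooth function.
    """
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    J = X.shape[1]
    if J not in (1, 2):
        raise ValueError("oracle supports 1 or 2 covariates")
    alpha = np.linspace(-10.0, 6.0, n_alpha)
    pa = np.exp(-0.5 * (alpha / intercept_sd) ** 2) / (
        np.sqrt(2 * np.pi) * intercept_sd)
    t = np.linspace(-6.0, 6.0, n_t)
    phi = np.exp(-0.5 * t * t) / np.sqrt(2 * np.pi)
    s_grid = np.linspace(1e-6, sigma_beta_upper, n_s)

    # null model: intercept only (sigma_beta integrates out of the prior)
    ll0 = _loglik_grid(y, n, alpha[:, None] * np.ones(len(y)))
    m0 = np.trapezoid(pa * np.exp(ll0), alpha)

    def single(j):
        """Marginal likelihood and E-numerator for the model {j} active."""
        m_s = np.empty(n_s)
        mb_s = np.empty(n_s)
        for k, s in enumerate(s_grid):
            eta = (alpha[:, None, None]
                   + (s * t)[None, :, None] * X[None, None, :, j])
            f = pa[:, None] * phi[None, :] * np.exp(_loglik_grid(y, n, eta))
            inner = np.trapezoid(f, alpha, axis=0)      # over alpha -> (t,)
            m_s[k] = np.trapezoid(inner, t)
            mb_s[k] = np.trapezoid(inner * s * t, t)
        u = 1.0 / sigma_beta_upper
        return (np.trapezoid(m_s, s_grid) * u, np.trapezoid(mb_s, s_grid) * u)

    if J == 1:
        m1, mb1 = single(0)
        z = m0 + m1
        return {"pr_include": np.array([m1 / z]),
                "mean_gb": np.array([mb1 / z])}

    m1, mb1 = single(0)
    m2, mb2 = single(1)

    # both active, shared sigma: integrate (alpha, t1, t2) per sigma value
    m_s = np.empty(n_s)
    mb1_s = np.empty(n_s)
    mb2_s = np.empty(n_s)
    for k, s in enumerate(s_grid):
        eta = (alpha[:, None, None, None]
               + (s * t)[None, :, None, None] * X[None, None, None, :, 0]
               + (s * t)[None, None, :, None] * X[None, None, None, :, 1])
        ll = _loglik_grid(y, n, eta)
        f = (pa[:, None, None] * phi[None, :, None] * phi[None, None, :]
             * np.exp(ll))
        inner = np.trapezoid(f, alpha, axis=0)          # (t1, t2)
        m_s[k] = np.trapezoid(np.trapezoid(inner, t, axis=0), t)
        mb1_s[k] = np.trapezoid(
            np.trapezoid(inner * (s * t)[:, None], t, axis=0), t)
        mb2_s[k] = np.trapezoid(
            np.trapezoid(inner * (s * t)[None, :], t, axis=0), t)
    u = 1.0 / sigma_beta_upper
    m12 = np.trapezoid(m_s, s_grid) * u
    mb1_12 = np.trapezoid(mb1_s, s_grid) * u
    mb2_12 = np.trapezoid(mb2_s, s_grid) * u

    z = m0 + m1 + m2 + m12
    pr = np.array([(m1 + m12) / z, (m2 + m12) / z])
    mean_gb = np.array([(mb1 + mb1_12) / z, (mb2 + mb2_12) / z])
    return {"pr_include": pr, "mean_gb": mean_gb}


def brute_force_components(coords, linkage):
    """Connected components of the <= linkage graph by explicit BFS."""
    coords = np.asarray(coords, float)
    m = len(coords)
    labels = -np.ones(m, dtype=int)
    current = 0
    for start in range(m):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = current
        while stack:
            i = stack.pop()
            for j in range(m):
                if labels[j] < 0 and np.hypot(*(coords[i] - coords[j])) <= linkage:
                    labels[j] = current
                    stack.append(j)
        current += 1
    return labels


def mc_disc_overlap(h, n_points=2_000_000, seed=12345):
    """Monte-Carlo normalized overlap area of two equal discs.

    The discs have radius R and centers 2*R*h apart, so the overlap
    vanishes at separation 2R (the kernel range).
    """
    rng = np.random.default_rng(seed)
    R = 1.0
    d = 2.0 * R * h
    lo, hi = -R, d + R
    pts = rng.uniform(lo, hi, size=(n_points, 2))
    in1 = (pts ** 2).sum(1) <= R ** 2
    in2 = (((pts - [d, 0.0]) ** 2).sum(1)) <= R ** 2
    box = (hi - lo) ** 2
    return (in1 & in2).mean() * box / (np.pi * R ** 2)
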