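"""Model fit and convergence diagnostics.

Two pseudo-R² flavours are provided: the binomial deviance ratio (the share
of the null deviance explained by the fitted probabilities, used for
in-sample fit) and Nagelkerke's rescaled likelihood-ratio index evaluated on
Bernoulli-expanded trap-night records (used for cross-validated
predictions).  Model adequacy is checked with a posterior-predictive χ²
discrepancy, and chain convergence with the potential-scale-reduction
statistic R-hat.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, xlogy

from .model import PosteriorSamples

_P_FLOOR = 1e-12


class DegenerateNullError(ValueError):
    """The pooled null model is degenerate (pooled rate is 0 or 1)."""


class DiagnosticError(ValueError):
    """A diagnostic's preconditions are not met (e.g. a single chain)."""


def _clamp(p):
    return np.clip(np.asarray(p, dtype=float), _P_FLOOR, 1.0 - _P_FLOOR)


def _check_lengths(y, n, p):
    y, n, p = np.asarray(y, float), np.asarray(n, float), np.asarray(p, float)
    if not (len(y) == len(n) == len(p)):
        raise ValueError("y, n and p_hat must have equal lengths")
    return y, n, p


def binomial_loglik(y, n, p) -> float:
    """Bernoulli-expansion log-likelihood (no combinatorial constant)."""
    p = _clamp(p)
    return float(np.sum(xlogy(y, p) + xlogy(n - y, 1.0 - p)))


def pseudo_r2_deviance(y, n, p_hat) -> float:
    """Share of the binomial deviance explained by the fitted model.

    ``(D_null - D_model) / D_null`` with deviances measured against the
    saturated model and the null model using the pooled capture rate;
    clamped below at 0 for worse-than-null fits.
    """
    y, n, p_hat = _check_lengths(y, n, p_hat)
    pooled = y.sum() / n.sum()
    if pooled <= 0.0 or pooled >= 1.0:
        raise DegenerateNullError(
            "pooled capture rate is 0 or 1; null deviance undefined")
    ll_sat = binomial_loglik(y, n, _clamp(y / n))
    ll_null = binomial_loglik(y, n, np.full_like(y, pooled, dtype=float))
    ll_model = binomial_loglik(y, n, p_hat)
    d_null = 2.0 * (ll_sat - ll_null)
    d_model = 2.0 * (ll_sat - ll_model)
    if d_null <= 0.0:
        raise DegenerateNullError("null deviance is zero")
    return max(0.0, (d_null - d_model) / d_null)


def pseudo_r2_nagelkerke(y, n, p_hat, clamp: bool = True) -> float:
    """Nagelkerke's rescaled pseudo-R² on Bernoulli-expanded data.

    ``(1 - (L0/L1)^(2/N)) / (1 - L0^(2/N))`` with N the total number of
    trap-nights and likelihoods evaluated per trap-night record; the null
    uses the pooled capture rate.  Clamped below at 0 on the reported
    scale; ``clamp=False`` exposes the raw (possibly negative) value, which
    permutation and ceiling comparisons need so that worse-than-null fits
    still rank against each other instead of tying at zero.
    """
    y, n, p_hat = _check_lengths(y, n, p_hat)
    N = n.sum()
    pooled = y.sum() / N
    if pooled <= 0.0 or pooled >= 1.0:
        raise DegenerateNullError(
            "pooled capture rate is 0 or 1; null likelihood degenerate")
    ll0 = binomial_loglik(y, n, np.full_like(y, pooled, dtype=float))
    ll1 = binomial_loglik(y, n, p_hat)
    r2_cs = 1.0 - np.exp((2.0 / N) * (ll0 - ll1))
    max_cs = 1.0 - np.exp((2.0 / N) * ll0)
    raw = float(r2_cs / max_cs)
    return max(0.0, raw) if clamp else raw


def chi2_discrepancy(y, n, p) -> float:
    """Pearson χ² discrepancy ``sum_i (y_i - n_i p_i)^2 / (n_i p_i (1 - p_i))``."""
    y, n, p = _check_lengths(y, n, p)
    p = _clamp(p)
    return float(np.sum((y - n * p) ** 2 / (n * p * (1.0 - p))))


def posterior_predictive_pvalue(samples: PosteriorSamples, seed: int = 0,
                                max_draws: int = 1000) -> float:
    """Bayesian p-value of the χ² discrepancy under posterior replication.

    For each retained draw, replicate counts ``y_rep ~ Binomial(n, p(θ))``
    and compare ``T(y_rep, θ)`` with ``T(y_obs, θ)``; the p-value is the
    fraction of draws where the replicated discrepancy is at least the
    observed one.  Values near 0 or 1 signal misfit.
    """
    eta = samples.linear_predictor_draws(max_draws=max_draws)
    if len(eta) < 100:
        raise DiagnosticError("need at least 100 retained draws")
    p = _clamp(expit(eta))
    y, n = samples.data.y, samples.data.n
    rng = np.random.default_rng(seed)
    y_rep = rng.binomial(n[None, :], p)
    t_obs = np.sum((y[None, :] - n * p) ** 2 / (n * p * (1 - p)), axis=1)
    t_rep = np.sum((y_rep - n * p) ** 2 / (n * p * (1 - p)), axis=1)
    return float(np.mean(t_rep >= t_obs))


def rhat(samples: PosteriorSamples | dict[str, np.ndarray]) -> dict[str, float]:
    """Potential-scale-reduction factor R̂ per continuous parameter.

    Uses the conservative pooled form ``sqrt(1 + var(chain means) / W)``
    with ``W`` the mean within-chain variance: exactly 1 for chains that
    agree perfectly, and inflated when chains sample different regions.
    Accepts either fitted :class:`PosteriorSamples` or a mapping of
    parameter name to a ``(chains, draws)`` array.
    """
    if isinstance(samples, PosteriorSamples):
        arrays: dict[str, np.ndarray] = {}
        for k, yr in enumerate(samples.data.years):
            arrays[f"alpha_{yr}"] = samples.alpha[:, :, k]
        arrays["sigma_beta"] = samples.sigma_beta
        if samples.spec.include_forest_effects:
            arrays["sigma_forest"] = samples.sigma_forest
        if samples.spec.include_site_effects:
            arrays["sigma_site"] = samples.sigma_site
    else:
        arrays = dict(samples)
    out: dict[str, float] = {}
    for name, arr in arrays.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise DiagnosticError(f"{name}: R-hat needs >= 2 chains")
        w = float(np.mean(np.var(arr, axis=1, ddof=1)))
        b = float(np.var(np.mean(arr, axis=1), ddof=1))
        out[name] = 1.0 if w == 0.0 and b == 0.0 else float(np.sqrt(1.0 + b / w))
    return out
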