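"""Spatially blocked cross-validation, permutation tests, ceiling simulation.

Cross-validation folds are blocks of sites: sites within 500 m of each
other always share a fold, so held-out predictions cannot borrow strength
from spatial autocorrelation.  Predictive skill is summarized by
Nagelkerke's pseudo-R² on the combined hold-out data and its significance
assessed by randomly permuting the vector of predictions across visits.

The ceiling simulation quantifies how much pseudo-R² is attainable at all
when capture events are rare: even a predictor equal to the true capture
probabilities scores low when one or two captures dominate the deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .diagnostics import DegenerateNullError, pseudo_r2_nagelkerke
from .domain import CaptureDataset, build_design_matrix
from .model import ModelSpec, PosteriorSamples, inclusion_probabilities, run_mcmc
from .spatial import allocate_folds, cluster_sites

__all__ = ["CVResult", "CeilingResult", "cross_validate",
           "permutation_pvalue", "ceiling_simulation"]


@dataclass
class CVResult:
    """Outcome of spatially blocked k-fold cross-validation."""

    predictions: pd.DataFrame          # site_id, year, fold, y, n, p_pred
    fold_of_site: dict[str, int]
    pseudo_r2: float                   # combined hold-out Nagelkerke
    per_fold_inclusion: list[dict[str, float]]
    permutation_p: float | None = None
    k: int = 10

    def inclusion_consistency(self, threshold: float = 0.75) -> dict[str, int]:
        """Number of folds in which each covariate exceeded the threshold."""
        names = self.per_fold_inclusion[0].keys()
        return {nm: sum(f[nm] > threshold for f in self.per_fold_inclusion)
                for nm in names}


@dataclass
class CeilingResult:
    """Distribution of pseudo-R² achievable at the given efforts and rates."""

    observed_r2: float | None
    simulated_r2: np.ndarray
    prob_le_observed: float | None

    @property
    def median_r2(self) -> float:
        return float(np.median(self.simulated_r2))


def _safe_nagelkerke(y, n, p, clamp: bool = True) -> float:
    """Nagelkerke pseudo-R², defined as 0 when the null is degenerate."""
    try:
        return pseudo_r2_nagelkerke(y, n, p, clamp=clamp)
    except DegenerateNullError:
        return 0.0


def _subset(dataset: CaptureDataset, keep: np.ndarray) -> CaptureDataset:
    visits = [v for v, k in zip(dataset.visits, keep) if k]
    return CaptureDataset(visits=visits,
                          covariate_names=dataset.covariate_names,
                          availability_mask=dataset.availability_mask)


def _holdout_predictions(samples: PosteriorSamples, test: CaptureDataset,
                         X_test: np.ndarray, max_draws: int = 1000) -> np.ndarray:
    """Posterior-mean capture probabilities for held-out visits.

    Held-out sites' spatial random effects sit at their prior mean (zero):
    the prediction is deliberately not informed by spatial autocorrelation.
    Forest effects, estimated from the training folds, are retained at
    their per-draw values (zero for forests absent from training).
    """
    d = samples.data
    alpha = samples.pooled("alpha")
    gb = samples.pooled("gamma") * samples.pooled("beta")
    epsf = samples.pooled("eps_forest")
    idx = np.arange(len(alpha))
    if len(idx) > max_draws:
        idx = idx[np.linspace(0, len(idx) - 1, max_draws).astype(int)]
    years = list(d.years)
    year_cols = np.empty((len(idx), len(test)), dtype=float)
    alpha_sel = alpha[idx]
    mean_alpha = alpha_sel.mean(axis=1)
    for j, v in enumerate(test.visits):
        if v.year in years:
            year_cols[:, j] = alpha_sel[:, years.index(v.year)]
        else:  # year unseen in training: fall back to the average intercept
            year_cols[:, j] = mean_alpha
    forest_cols = np.zeros((len(idx), len(test)), dtype=float)
    forests = list(d.forest_ids)
    epsf_sel = epsf[idx]
    for j, v in enumerate(test.visits):
        if v.forest_id in forests:
            forest_cols[:, j] = epsf_sel[:, forests.index(v.forest_id)]
    eta = year_cols + gb[idx] @ X_test.T + forest_cols
    return expit(eta).mean(axis=0)


def cross_validate(dataset: CaptureDataset, spec: ModelSpec, k: int = 10,
                   seed: int = 0, linkage_m: float = 500.0,
                   n_perm: int | None = 999) -> CVResult:
    """Spatially blocked k-fold cross-validation of the capture model.

    Sites are clustered by single linkage at ``linkage_m`` and clusters
    dealt into ``k`` folds, so all surveys of a site — and all sites within
    the linkage distance of one another — share a fold.  Each fold is
    predicted from a model refit on the remaining sites, with covariate
    standardization recomputed on training data only.  Returns the combined
    hold-out Nagelkerke pseudo-R², per-fold inclusion probabilities, and
    (when ``n_perm`` is set) the permutation p-value of the pseudo-R².
    """
    site_ids, coords = dataset.site_coordinates()
    clusters = cluster_sites(coords, linkage_m)
    fold_per_site = allocate_folds(clusters, k, seed)
    fold_of_site = {str(s): int(f) for s, f in zip(site_ids, fold_per_site)}
    visit_fold = np.array([fold_of_site[v.site_id] for v in dataset.visits])

    records = []
    per_fold_incl = []
    fold_seeds = [int(s.generate_state(1)[0] % (2**31))
                  for s in np.random.SeedSequence(seed).spawn(k)]
    for f in range(k):
        test_mask = visit_fold == f
        train = _subset(dataset, ~test_mask)
        test = _subset(dataset, test_mask)
        design = build_design_matrix(train)
        fold_spec = replace(spec, seed=fold_seeds[f])
        samples = run_mcmc(train, fold_spec, design=design)
        if samples.data.y.sum() == 0:
            warnings.warn(f"fold {f}: no captures in training data",
                          stacklevel=2)
        per_fold_incl.append(inclusion_probabilities(samples))
        if len(test) == 0:
            continue
        X_test = design.transform(test)[:, [design.covariate_names.index(c)
                                            for c in spec.covariates]]
        p = _holdout_predictions(samples, test, X_test)
        for v, pi in zip(test.visits, p):
            records.append({"site_id": v.site_id, "year": v.year, "fold": f,
                            "y": v.counts[spec.response_class],
                            "n": v.effort, "p_pred": float(pi)})
    preds = pd.DataFrame.from_records(records)
    r2 = _safe_nagelkerke(preds["y"].to_numpy(), preds["n"].to_numpy(),
                          preds["p_pred"].to_numpy())
    perm_p = None
    if n_perm:
        perm_p = permutation_pvalue(preds["y"].to_numpy(), preds["n"].to_numpy(),
                                    preds["p_pred"].to_numpy(),
                                    n_perm=n_perm, seed=seed)
    return CVResult(predictions=preds, fold_of_site=fold_of_site,
                    pseudo_r2=r2, per_fold_inclusion=per_fold_incl,
                    permutation_p=perm_p, k=k)


def permutation_pvalue(observed_y, n, held_out_p, n_perm: int = 999,
                       seed: int = 0) -> float:
    """Probability of an equal-or-higher pseudo-R² under permuted predictions.

    The vector of held-out predictions is randomly permuted across visits
    ``n_perm`` times; the p-value uses the add-one formulation
    ``(1 + #{permuted R² >= observed R²}) / (n_perm + 1)`` so it is never 0.
    Ranking uses the unclamped pseudo-R² so that permutations worse than
    the null model do not all tie at zero (which would make null p-values
    degenerate instead of uniform).
    """
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    y = np.asarray(observed_y, float)
    n = np.asarray(n, float)
    p = np.asarray(held_out_p, float)
    if np.ptp(p) == 0.0:
        warnings.warn("constant predictions: permutation test degenerate",
                      stacklevel=2)
        return 1.0
    observed = _safe_nagelkerke(y, n, p, clamp=False)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r2 = _safe_nagelkerke(y, n, rng.permutation(p), clamp=False)
        if r2 >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def ceiling_simulation(n, p_pred, observed_r2: float | None = None,
                       y_obs=None, n_sims: int = 1000,
                       seed: int = 0) -> CeilingResult:
    """How much pseudo-R² perfect predictions could achieve at these efforts.

    Replicate counts are simulated as ``y_sim ~ Binomial(n, p_pred)`` — i.e.
    the predictions are treated as the true capture probabilities — and the
    pseudo-R² of ``p_pred`` against each replicate recorded.  If an observed
    pseudo-R² (or observed counts) is supplied, also reports
    ``Pr(simulated <= observed)``: a value near 0.5 means the observed skill
    is as high as the sampling noise permits.
    """
    if n_sims < 500:
        raise ValueError("n_sims must be >= 500")
    n = np.asarray(n, dtype=int)
    p = np.asarray(p_pred, float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p_pred must lie strictly inside (0, 1)")
    observed_raw = observed_r2
    if observed_r2 is None and y_obs is not None:
        observed_raw = _safe_nagelkerke(np.asarray(y_obs, float), n, p,
                                        clamp=False)
        observed_r2 = max(0.0, observed_raw)
    rng = np.random.default_rng(seed)
    sims_raw = np.empty(n_sims)
    for s in range(n_sims):
        y_sim = rng.binomial(n, p)
        # raw (unclamped) values so the rank comparison has no ties at 0
        sims_raw[s] = _safe_nagelkerke(y_sim, n, p, clamp=False)
    prob = None
    if observed_raw is not None:
        prob = float(np.mean(sims_raw <= observed_raw))
    return CeilingResult(observed_r2=observed_r2,
                         simulated_r2=np.maximum(sims_raw, 0.0),
                         prob_le_observed=prob)
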