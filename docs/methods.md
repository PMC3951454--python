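# Methods

## The model

`capturebayes` models small-mammal trapping data in which each visit to a
0.25 ha site yields a count of distinct individuals captured over
`n = traps × nights` trap-nights. Each trap-night is a Bernoulli trial, so
a visit contributes a binomial observation. For visit *i*:

    y_i ~ Binomial(n_i, p_i)
    logit(p_i) = α_year(i) + Σ_j γ_j β_j x_ij + ε_forest(i) + ε_site(i)

* `α_year` — year-specific intercepts, the logit-scale mean capture rates.
  Prior N(0, 10²): effectively flat over any plausible capture rate while
  remaining proper (the intercept prior was a genuinely open choice; a
  10-SD normal on the logit scale is vague without the numerical pathologies
  of an improper prior).
* `x_j` — standardized covariates: stand-condition score, distance to
  floodwaters (km), fallen-timber volume (m³/ha), previous-year rainfall
  (mm), orb-web counts, and two 0/1 life-stage indicators (January =
  juvenile dispersal, March–May = post-juvenile dispersal; June–July
  breeding-season visits are the reference level). Continuous covariates
  are centered and scaled to unit SD over all non-missing values before
  fitting; a single exchangeable prior across covariates measured in km,
  mm and m³/ha is only meaningful on a common scale. Covariate-years that
  were never collected (orb webs before 2011) are mean-imputed to 0 on the
  standardized scale and flagged in an availability mask, so they
  contribute nothing to the linear predictor where absent.
* `β_j ~ N(0, σ_β²)`, `σ_β ~ Uniform(0, u)` with `u = 2` by default and a
  sensitivity sweep over `u ∈ {0.3, 1, 2, 4}` available
  (`sensitivity_refits`, `capturebayes fit --sensitivity-sweep`).
* `γ_j ~ Bernoulli(1/2)` — covariate-inclusion indicators. The posterior
  mean of `γ_j` is the posterior probability Pr(β_j ≠ 0) that covariate
  *j* belongs in the model. With unity prior odds, Pr > 0.75 corresponds
  to at least a threefold gain in odds and is flagged as a strong effect
  (`evidence_threshold(1, 3) = 0.75`).
* `ε_forest ~ N(0, σ_forest²)` exchangeably across forests;
  `ε_site ~ MVN(0, σ_site² R)` where `R` is built from the disc kernel
  (below). Both SDs get Uniform(0, 5) priors.

Each of the five response classes (all individuals, males, females,
second-year females, second-year females with suckled teats) is fitted as
a separate model with the same structure.

## The disc kernel

Site random effects are correlated through the two-dimensional disc
(circular) correlation: with `h = d / range`,

    ρ(h) = (2/π) (arccos h − h √(1 − h²)),   ρ = 0 for h ≥ 1

— the normalized overlap area of two equal discs whose overlap vanishes at
the range (500 m by default, the scale of an antechinus home range). This
function declines nearly linearly over most of its support (its maximal
deviation from the chord 1 − h on h ∈ [0.2, 0.8] is below 0.12) and, being
an overlap-area kernel, is positive definite in the plane — unlike a
truncated-linear kernel, which is not a valid 2-D correlation. A relative
jitter of 1e-8 is added to covariance diagonals for Cholesky stability.

## Sampling

The sampler is Metropolis-within-Gibbs, bit-for-bit reproducible given
`(seed, spec, data)`; per-chain generators derive deterministically from
the spec seed.

* **Variable selection.** `γ_j` is updated by a Gibbs step. Because an
  inactive coefficient is refreshed from the pseudo-prior N(0, σ_β²) —
  identical to its conditional prior — the indicator's conditional odds
  reduce to a likelihood ratio, and the sampler's stationary distribution
  coincides with that of a trans-dimensional (reversible-jump) sampler
  over the nested models. This within-model formulation was chosen over
  literal birth/death moves because it is far easier to verify against a
  quadrature oracle, which the test suite does on a 4-visit fixture.
* **Coefficients and intercepts.** Scalar random-walk Metropolis, with
  intercept updates evaluated only on the affected year's visits.
* **Random effects.** Sampled in non-centered form (`ε = σ L u`,
  `u ~ N(0, I)`, `L` the correlation Cholesky) with preconditioned
  Crank–Nicolson block proposals, for which the Gaussian prior cancels
  exactly from the acceptance ratio. The SDs are updated twice per
  iteration: once in the non-centered parameterization (likelihood-driven)
  and once interweaved in the centered one (prior-driven, holding `ε`
  fixed and rescaling `u`), which removes the funnel-shaped slow mixing
  that either parameterization alone exhibits when the SD is small.
* **Translation move.** A joint proposal shifts all year intercepts by δ
  and compensates the forest effects by −δ/σ_forest. The likelihood is
  invariant, so acceptance depends only on the priors; this decorrelates
  the intercepts from the forest-effect mean, which otherwise mix slowly.
* **Adaptation.** Robbins–Monro tuning of proposal scales (targets 0.44
  for scalar moves, 0.25 for blocks) runs during burn-in only and is
  frozen afterwards, preserving detailed balance of the retained draws.
* **Initialization.** Intercepts at the empirical logit of the pooled
  capture rate, β = 0, γ = 1, SDs at half their prior upper bounds.

The default schedule is desk-scale — 3 chains × 8 000 iterations with
2 000 burn-in — chosen as the package's standard operating point for
synthetic data; at this schedule all monitored R̂ values on study-scale
fits are below 1.05. The field-scale schedule (3 × 150 000 / 50 000) is
available through `ModelSpec(iterations=150000, burn_in=50000)`.

## Fit and adequacy metrics

* **Deviance pseudo-R²** (in-sample): `(D_null − D_model)/D_null`, the
  share of the binomial deviance explained relative to the saturated
  model, with the null using the pooled capture rate for the response
  class (pooled over all visits, not per year — an explicit assumption).
  Computed at the draw-averaged fitted probabilities `E[p_i | y]`;
  conditioning on posterior means of the parameters instead is the main
  alternative and gives very similar values on synthetic fits.
* **Nagelkerke pseudo-R²** (cross-validation):
  `(1 − (L0/L1)^(2/N)) / (1 − L0^(2/N))` with `N` the total number of
  trap-nights and likelihoods evaluated on Bernoulli-expanded records.
  Both pseudo-R² flavours are clamped at 0 on the reported scale; the
  permutation and ceiling procedures rank with the unclamped statistic,
  because with clamping every worse-than-null permutation ties at zero
  and a null p-value degenerates to 1 instead of being uniform.
* **Posterior-predictive check**: per retained draw, replicate counts
  `y_rep ~ Binomial(n, p(θ))` and the Pearson χ² discrepancy
  `Σ (y − np)²/(np(1−p))` are compared for replicated vs observed data;
  the Bayesian p-value is the fraction of draws with `T(y_rep) ≥ T(y_obs)`.
  Probabilities are floored at 1e-12 so boundary fits stay finite.
* **R̂**: the conservative pooled form `sqrt(1 + var(chain means)/W)`,
  exactly 1 for chains that agree perfectly; values above 1.1 trigger a
  prominent warning in the CLI report.

## Spatially blocked cross-validation

Sites are clustered by single linkage at 500 m (connected components of
the ≤ 500 m graph), clusters are shuffled and dealt round-robin into k
folds (default 10), so all surveys of a site — and all sites within 500 m
of one another — share a fold, and fold sizes in clusters differ by at
most one. Each fold is predicted from a refit on the remaining sites,
with covariate standardization recomputed on training data only. Held-out
site effects are set to their prior mean (zero): predictions are
deliberately not informed by spatial autocorrelation. Forest effects are
retained at their training posterior values, since every forest remains
represented in training and forest membership is not the spatial-leakage
channel the blocking removes. Predictive significance uses a global
permutation of the held-out prediction vector (999 permutations by
default, add-one p-value so p is never 0); permuting within year is the
alternative, not implemented.

## Ceiling simulation

With capture probabilities of order 10⁻³–10⁻², one or two captures move
the deviance substantially, capping the pseudo-R² any predictor can
attain. `ceiling_simulation` treats the predictions as the true
probabilities, simulates replicate counts at the actual efforts, and
reports the distribution of pseudo-R² plus Pr(simulated ≤ observed). When
the observed data really do come from the predictions, that probability
sits near 1/2 by exchangeability; the attainable median pseudo-R²
decreases monotonically as capture rates fall, which is why rare-class
capture rates are too low to estimate density differences precisely.

## Synthetic data

The generator reproduces the study design: 272 sites of 0.25 ha across 7
forests (disjoint rectangles, 4 km side, 10 km apart so cross-forest
correlation vanishes), placed by rejection sampling at > 300 m spacing;
5–6 traps for 1–5 nights with Pr(nights ≥ 2) = 0.83 (single-night
probability 0.17, 2–5 nights equiprobable otherwise); 2004 sites revisited
in 2005, 72 fresh sites in two forests in 2011. Covariates are truncated
normals at the per-year means/SDs observed in the study; orb-web counts
are gamma-Poisson (mean 4, SD 5.1) and exist only in 2011; 2011 sites all
sit at distance 0 from floodwaters. Year intercepts default to the
study's logit-scale capture rates (−2.97, −2.31, −2.16) and covariate
coefficients to the study's reported posterior means for total captures.

Total counts are drawn from the model itself (including forest and
disc-correlated site effects); individuals are then thinned male/female
(male odds reduced after juvenile dispersal), females to second-year (odds
increasing with stand condition), and second-year to suckled-teats (0.94,
so at least 6% of second-year females show no weaning). The nested-count
invariants hold by construction and each class has its own effective
coefficients. Default split rates put second-year-female capture rates at
roughly 0.002–0.006 per trap-night, the rare-event regime of the study.

What the generator does *not* emulate: real geography (only pairwise
distances matter to the model), spatially smooth covariate fields,
temporal carry-over in animal numbers between years, inter-covariate
correlation, and non-binomial capture processes (trap saturation,
behavioural responses). Passing recovery tests therefore certify the
estimation machinery under the model's own assumptions, not robustness to
the field data's unmodeled structure.

Recovery experiments in the tests and the acceptance script use a truth
with two real effects (Condition 0.8, fallen timber 0.5, standardized
scale) and five exact zeros, a clearly detectable signal at the study's
design scale; experiment sizes are 20 datasets in the tests and 10 in the
acceptance script, with cross-validation run on 60-site studies at a
shortened 2-chain schedule — sizes chosen as the package's standard
desk-scale experiment.

## Known limitations

* Proposal adaptation is frozen at burn-in; very short burn-ins can leave
  scales poorly tuned (symptom: low acceptance in `samples.acceptance`).
* `σ_site` is weakly identified at the study's sparse effort (1–2 visits
  per site); its posterior concentrates well below a true 0.3, though the
  spatial-signal ordering is still detected in paired comparisons.
* The quadrature oracle covers at most 2 covariates and no random
  effects; sampler correctness for the full model rests on that oracle
  plus recovery and calibration experiments.
* Prior sensitivity is a refit sweep, not an integrated analysis.
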