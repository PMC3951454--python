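# capturebayes

Hierarchical Bayesian analysis of small-mammal capture rates against
remotely sensed forest-stand condition.

Ecologists monitoring floodplain forests want to know whether a
satellite-derived stand-condition score predicts the density of an animal
population — here, the yellow-footed antechinus trapped at hundreds of
0.25 ha sites across river red gum forests. The data are counts of
distinct individuals captured over `n = traps × nights` trap-nights per
site visit, in five nested response classes (all individuals, males,
females, second-year females, second-year females with suckled teats).
`capturebayes` provides the full analysis chain for such data: the model,
its model-checking machinery, and a synthetic-data generator that emulates
the study design so every stage is testable without the field data.

## The model

Each trap-night is a Bernoulli trial:

    y_i ~ Binomial(n_i, p_i)
    logit(p_i) = α_year(i) + Σ_j γ_j β_j x_ij + ε_forest(i) + ε_site(i)

with year-specific intercepts, standardized covariates (stand condition,
distance to floodwaters, fallen-timber volume, previous-year rainfall,
orb-web counts, and life-stage indicators), exchangeable forest random
effects, and site random effects correlated by a 2-D disc kernel that
declines nearly linearly to zero at 500 m. Bayesian variable selection
puts a Bernoulli(1/2) indicator γ_j on each covariate; the posterior
Pr(β_j ≠ 0) measures the evidence that covariate j predicts the response,
and Pr > 0.75 (a threefold gain on unity prior odds) flags a strong
effect. Priors: β_j ~ N(0, σ_β²) with σ_β ~ U(0, 2) (sensitivity sweep
over upper limits 0.3/1/2/4), σ_site, σ_forest ~ U(0, 5).

Model checking includes posterior-predictive χ² discrepancy, deviance and
Nagelkerke pseudo-R², spatially blocked 10-fold cross-validation (sites
within 500 m always share a fold), permutation tests of predictive skill,
and a capture-ceiling simulation quantifying how much pseudo-R² is even
attainable when captures are rare. See `docs/methods.md` for details.

## Worked example

Generate a synthetic study (272 sites, 7 forests, 2004/2005 revisits plus
new 2011 sites) with two real effects — stand condition 0.8 and fallen
timber 0.5 on the standardized logit scale — and fit the total-captures
model:

```python
import capturebayes as cb

cfg = cb.GeneratorConfig(seed=2, beta={"Condition": 0.8, "Logs": 0.5,
                                       "FloodDist": 0, "RainPrevYr": 0,
                                       "Webs": 0, "JD": 0, "PostJD": 0})
dataset, truth = cb.generate_dataset(cfg)
samples = cb.run_mcmc(dataset, cb.ModelSpec(seed=3))
print(cb.posterior_summary(samples).round(3).to_string(index=False))
```

```
 parameter   mean    sd  pr_nonzero  strong
alpha_2004 -2.848 0.269         NaN   False
alpha_2005 -2.326 0.264         NaN   False
alpha_2011 -2.350 0.297         NaN   False
 Condition  0.722 0.045       1.000    True
 FloodDist  0.000 0.013       0.071   False
      Logs  0.500 0.041       1.000    True
RainPrevYr -0.016 0.041       0.184   False
      Webs  0.056 0.103       0.330   False
        JD  0.025 0.062       0.221   False
    PostJD -0.017 0.053       0.186   False
```

The intercepts recover the generator's logit-scale capture rates (−2.97,
−2.31, −2.16 for p ≈ 0.05–0.10 per trap-night); the two real effects are
recovered near their true values with Pr(β ≠ 0) = 1.0 and flagged strong,
while the five noise covariates stay near their prior mean of 0 with
Pr well below the 0.75 threshold. Fit metrics from the same run:

```python
p_hat = samples.fitted_p()
cb.pseudo_r2_deviance(samples.data.y, samples.data.n, p_hat)  # 0.611
cb.posterior_predictive_pvalue(samples, seed=0)               # 0.78
max(cb.rhat(samples).values())                                # 1.047
```

— the model explains 61% of the binomial deviance, the posterior-predictive
p-value is interior (no evidence of misfit), and all chains agree.

The same pipeline is scriptable from the shell:

```
capturebayes simulate --seed 4 --out runs/sim
capturebayes fit      --input runs/sim/visits.csv --response f2 --out runs/fit
capturebayes validate --input runs/sim/visits.csv --folds 10 --out runs/val
```

`fit` writes a coefficient table (`summary.csv`), the posterior draws, and
a metrics report; `validate` writes fold assignments, held-out
predictions, the cross-validated pseudo-R² with its permutation p-value,
and the ceiling simulation.

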