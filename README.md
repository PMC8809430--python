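# vulturesurvey

Bayesian state-space analysis of monthly, multi-site vulture point-count
surveys, with the accompanying questionnaire statistics.  The package is
aimed at raptor-monitoring analysts who have effort-varying count series
from fixed vantage points (for example monthly surveys of feeding and
roosting sites) and want an index of relative abundance that separates true
population fluctuation from survey noise.

## The model

For each species, latent relative abundance N at site *s* and month *t*
follows a Markovian random walk on the log scale,

    log N_{t+1,s} = log N_{t,s} + r_{t,s},     r_{t,s} ~ Normal(mu_r, sigma_proc^2),

so `sigma_proc` is the **process error** (real month-to-month change) and
`mu_r` the mean monthly log-growth.  Observed counts are Poisson with an
effort-adjusted, overdispersed mean,

    y_{t,s} ~ Poisson(lambda_{t,s}),
    log lambda_{t,s} = log N_{t,s} + B x_{t,s} + eta_{t,s},
    eta_{t,s} ~ Normal(0, sigma_obs^2),

where `x` is survey duration scaled and centered to mean 0 / SD 1, `B` its
shared coefficient, and `sigma_obs` the **observation error**.  Priors are
vague (normal(0, 10^2) on `mu_r`, `B` and initial log-abundances;
uniform(0, 10) on both SDs) and user-overridable.  Sampling is by
Metropolis-within-Gibbs (three chains of 300,000 iterations, 150,000
burn-in, thinning 50 by default — 3,000 retained draws per chain; a
desk-scale 20,000/10,000/thin-10 schedule is one call away).  Convergence
is declared when every Gelman–Rubin R-hat < 1.1, and model adequacy is
assessed through the **error ratio** `sigma_obs / sigma_proc`: the report
includes P(ratio > 10) against the 0.90 rule.  Relative-abundance reports
are median / 2.5th / 97.5th percentiles of the pooled latent-N draws, per
species and per site; cross-species site totals are summed draw-by-draw
before summarizing.

Questionnaire responses (age, gender, education, binary knowledge items)
are tested with from-scratch implementations of the two-tailed Fisher exact
test (sum-of-small-p convention, log-gamma arithmetic) and the
tie-corrected Kruskal–Wallis test.

A seeded synthetic-data module generates surveys from exactly this
generative model (11 sites, 12 monthly surveys of 2–4 h, seven species by
default) plus 300-respondent questionnaire tables, so the whole pipeline is
testable without field data.

## Worked example

```python
import vulturesurvey as vs

dataset, truth = vs.simulate_counts(vs.recovery_sim_params(seed=42))
draws = vs.run_mcmc(dataset, config=vs.MCMCConfig.desk_scale(seed=42))
diag = vs.compute_diagnostics(draws)
row = vs.species_relative_abundance(draws)
b = vs.effort_coefficient_summary(draws)
print("converged:", diag.converged, " max R-hat:", round(max(diag.rhat.values()), 3))
print("P(error ratio > 10):", diag.p_error_ratio_gt_threshold)
print(f"{row.species}: n_obs={row.n_observations}  "
      f"2.5%={row.pct_2_5:.2f}  median={row.median:.2f}  97.5%={row.pct_97_5:.2f}")
print(f"effort coefficient B: median={b.median:.3f}  "
      f"CI=({b.pct_2_5:.3f}, {b.pct_97_5:.3f})  P(B>0)={b.p_positive:.3f}")
```

prints

```
converged: True  max R-hat: 1.043
P(error ratio > 10): 0.0
White-rumped Vulture: n_obs=3303  2.5%=1.64  median=17.56  97.5%=79.29
effort coefficient B: median=0.283  CI=(0.191, 0.378)  P(B>0)=1.000
```

The simulated year of surveys totalled 3,303 birds counted; the pooled
posterior of latent abundance has median 17.6 birds per site-month with a
wide 95% interval (sites were seeded between 5 and 40 birds).  The chains
pass the R-hat rule, the error-ratio probability shows observation error
does not dominate (the generating ratio is 0.3/0.2 = 1.5), and the 95%
credible interval for the effort coefficient covers its generating value
of 0.3.

The same pipeline runs from the shell:

```
vulturesurvey simulate --seed 7 --out runs/sim
vulturesurvey fit --data runs/sim/survey_data.csv --desk-scale --seed 7 --out runs/fit
vulturesurvey diagnose --draws runs/fit/draws_White-rumped_Vulture.npz --out runs/diag.json
vulturesurvey summarize --draws runs/fit/draws_White-rumped_Vulture.npz --out runs/summ
vulturesurvey survey-stats --data runs/sim/respondents.csv --out runs/tests.csv
```

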