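# dsempanel

Dynamic structural equation modelling (DSEM) of weekly sleep and mood
panels, for researchers analysing intensive longitudinal data from
mood-monitoring cohorts — e.g. people with bipolar disorder completing
weekly insomnia, depression and (hypo)mania questionnaires over many
months.

The central question such panels can answer is *dynamic*: when a person's
sleep deviates from their own usual level this week, does their mood
deviate next week — and vice versa, and for whom?  `dsempanel` fits the
multilevel bivariate AR(1) model that separates these within-person
dynamics from stable between-person differences:

    Y_ijt = μ_ij + s_ij (t − t̄) + y_ijt
    y_ijt = Σ_k φ_jk,i · y_ik,t−1 + e_ijt,   e_ijt ~ N(0, π_ij)
    η_i = (μ_i, vec φ_i, log π_i, s_i) ~ N(γ + B x_i, Ω)

Every dynamic parameter is a person-specific random effect: the individual
mean μ, the inertia φ_jj (carry-over of a deviation to the next week), the
cross-lagged effects φ_jk, the (log) innovation variance π, and a small
linear trend s.  Estimation is Bayesian MCMC with data augmentation for
missing weeks; cross-lagged effects are reported as *average individually
standardised* estimates — standardised per person by that person's
stationary within-person standard deviations, then averaged — and can be
contrasted across strata defined by binary baseline covariates (bipolar
subtype, gender, age ≥ 55, history of rapid cycling).

The package also contains the questionnaire scoring (QIDS-SR16 with the
insomnia items split out; ASRM without the reduced-need-for-sleep item),
panel handling with explicit weekly grids and eligibility filtering, and a
calibrated synthetic-panel generator that serves as the ground-truth
oracle for every estimator in the test suite.

## Worked example

```python
import dsempanel as dp

# a calibrated synthetic cohort: 100 participants, 91 weekly occasions
spec = dp.calibrated_spec(("dep",))
panel, truth = dp.simulate_panel(dp.GeneratorConfig(spec=spec, n=100, n_weeks=91, seed=42))

res = dp.DsemModel(panel, processes=("dep",)).fit(chains=2, iterations=1000, burn=1000, seed=0)
print(res.summary())
```

```
Dynamic structural equation model (multilevel AR(1))
processes: dep   participants: 100   weeks: 91
chains: 2   draws/chain: 1000   seed: 0
covariates: none
RW acceptance (log innovation): 0.35
non-stationary lag proposals rejected: 1

                      mean         sd     median     ci_2.5    ci_97.5  p_one_tailed        psr
parameter
mu_dep              6.3744     0.4550     6.3765     5.4964     7.2740        0.0000     1.0002
phi_dep_dep         0.5009     0.0185     0.5005     0.4644     0.5372        0.0000     1.0002
logv_dep            2.2316     0.0513     2.2298     2.1365     2.3347        0.0000     1.0001
slope_dep          -0.0030     0.0029    -0.0029    -0.0092     0.0024        0.1395     1.0043
var_mu_dep         19.5065     2.9015    19.2907    14.3935    25.6732        0.0000     1.0013
var_phi_dep_dep     0.0236     0.0049     0.0232     0.0154     0.0339        0.0000     1.0006
var_logv_dep        0.2602     0.0410     0.2571     0.1905     0.3514        0.0000     1.0000
var_slope_dep       0.0001     0.0001     0.0001     0.0000     0.0003        0.0000     1.0345
```

Reading the table: the cohort's average stable depression level is 6.4
points (the generator's fixed effect is 7.33; this 100-person sample drew
a slightly low cohort), with substantial between-person heterogeneity
(`var_mu_dep` ≈ 19.5).  Depression deviations carry over week to week
with inertia ≈ 0.50, and people differ in that inertia
(`var_phi_dep_dep` ≈ 0.024, i.e. SD ≈ 0.15).  The population trend is a
statistically unconvincing −0.003 points/week.  All potential scale
reduction values are ≈ 1, so the two chains agree.

For a bivariate analysis, fit two processes and summarise the cross-lags
on the standardised scale:

```python
res2 = dp.DsemModel(panel2, processes=("dep", "ins")).fit(seed=0)
res2.random_effect_correlations()          # between-person correlation matrix
std = dp.average_standardised_effects(res2)
std.summary_frame()                        # averaged standardised cross-lags
dp.stratified_compare(fit_bd1, fit_bd2, effect=("ins", "dep"))  # stratum contrast
```

A command-line pipeline mirrors the three analytical steps
(`dsempanel simulate | step1 | step2 | step3 | report`); every run writes
a manifest (config, seed, version, input digest) and a log recording
exclusions, rejection rates and convergence flags.

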