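# Methods

`dsempanel` implements a multilevel dynamic structural equation model
(DSEM) for weekly symptom panels — the model class used to study the
interplay of insomnia, depression and (hypo)mania in bipolar-disorder
mood-monitoring cohorts — together with a calibrated synthetic-panel
generator, a purpose-built MCMC sampler, and the postprocessing that turns
posterior draws into averaged individually standardised cross-lag effects
and stratified contrasts.

## Model

For participant i, process j (one or two of depression, insomnia,
(hypo)mania) and week t = 1..T, the observed score decomposes as

    Y_ijt = mu_ij + s_ij (t - tbar) + y_ijt
    y_ijt = sum_k phi_jk,i y_ik,t-1 + e_ijt,   e_ijt ~ N(0, pi_ij)

with tbar = (T+1)/2.  The deviations y are the within-person dynamic
component; mu_ij is the individual mean (the person's stable level),
s_ij a person-specific linear trend (a nuisance accommodating the modest
population-level drift in long panels), phi_jj,i the inertia (carry-over
of a deviation to the next week), phi_jk,i the cross-lagged effect of the
other process's deviation, and pi_ij the innovation variance, modelled on
the log scale.  The person parameter vector

    eta_i = (mu_i, vec phi_i, log pi_i, s_i)      (4 or 10 entries)

is multivariate normal between persons, eta_i ~ N(gamma + B x_i, Omega),
truncated to the stationary region (spectral radius of phi_i below 1),
with x_i the four binary baseline covariates (BD-II vs BD-I, female, age
>= 55, history of rapid cycling).  Innovations are independent across
processes within a week (diagonal innovation covariance); a within-week
residual covariance is not modelled.  Missingness is assumed missing at
random; missing weeks are model parameters imputed by data augmentation.

The trend is centred at the grid midpoint so mu keeps its interpretation
as the mid-study stable level.  Standardisation of the lag coefficients
is per person: phi*_jk,i = phi_jk,i * sigma_ik / sigma_ij, where sigma are
the stationary within-person standard deviations of the trend-free
deviations, obtained from the discrete Lyapunov equation
Sigma = Phi Sigma Phi' + Psi.  The *average individually standardised*
effect is the across-person average of phi*, computed per posterior draw
and then summarised over draws, so that its credible interval reflects
both person-level and posterior uncertainty.  Person-draws outside the
stationary region have no stationary scale and are excluded from that
draw's average; the exclusion fraction is logged and a warning is raised
above 5%.

## Estimation

Metropolis-within-Gibbs, vectorised across participants:

1. **Data augmentation.** The pre-first-week deviation y_i0 is a latent
   parameter with a fixed N(0, diag v0) prior, v0 the pooled within-person
   variance of each process (an empirical initial-condition prior that
   matches the stationary scale while keeping every full conditional
   coherent with a single joint model).  Missing weeks are drawn from
   their Gaussian full conditionals in an odd/even-week schedule so that
   neighbouring missing weeks are never updated simultaneously; fully
   missing weeks get a joint p-dimensional draw, partially missing weeks a
   componentwise draw.
2. **(mu_i, s_i)** — joint conjugate normal draw per person (the
   transition residuals are linear in both).
3. **phi_i** — joint conjugate normal draw of the whole lag matrix
   (likelihood block-diagonal over rows given diagonal innovations, prior
   coupling from Omega).  Draws with spectral radius >= 1 are rejected and
   the current value kept, which is the exact Metropolis step for the
   truncated prior.
4. **log pi_ij** — random-walk Metropolis with per-person step sizes
   adapted during burn-in towards 35% acceptance.
5. **gamma, B** — joint conjugate normal draw (diffuse N(0, 1e4) priors;
   N(0, 10) for the log-innovation means).
6. **Omega** — Huang–Wand hierarchical inverse-Wishart: Omega | a ~
   IW(nu + q - 1, 2 nu diag(1/a)), a_k ~ inverse-gamma(1/2, 1/A^2), with
   nu = 2 and A = 25, giving half-t(2, 25) marginals on random-effect
   standard deviations and marginally uniform correlations.

The Omega prior deserves a note.  The random-effect variances in this
model span six orders of magnitude (individual means ~21 points^2, slopes
~1e-5); a plain inverse-Wishart with any fixed scale matrix distorts the
correlations of components whose variance sits far from that scale — an
identity scale shrinks the cross-lag correlation towards 0, while a small
scale inflates it towards 1.  During development both distortions were
measured against an independent oracle (per-person least-squares cross-lag
estimates deconvolved by maximum likelihood); the hierarchical prior
removed them, with the posterior matching the oracle to ~0.01.

Defaults are 2 chains of 2,000 retained iterations after 2,000 burn-in.
Convergence is monitored by the potential scale reduction
R = sqrt((W + B/n)/W) (within/between-chain variances) for every fixed
effect, covariate coefficient and random-effect variance, threshold 1.1;
a failed check sets the convergence flag false and warns, never silently.
Effective sample sizes come from arviz.  Identical (data, seed, chains,
iterations) reproduce draws bit-exactly.  Posterior p-values are
one-tailed, min(P(draw>0), P(draw<0)); stratum contrasts pair independent
draws from the two strata (one stream reversed so the pairing is
exchangeable) and report two-tailed p = 2 min(P(diff>0), P(diff<0)).

## Questionnaire scoring

Insomnia is the sum of the three QIDS-SR16 insomnia items (0–9).  The
depression score is the standard nine-domain QIDS total with those three
items removed; the sleep domain then reduces to the hypersomnia item
alone, preserving the 0–27 frame (an option drops the sleep domain
entirely, 0–24 — the instrument's published scoring is ambiguous on this
point once items are removed, and the hypersomnia-retaining variant is the
default because only the three insomnia items are explicitly removed).
The (hypo)mania score is the ASRM total with the reduced-need-for-sleep
item removed (0–16; 0–20 when retained).  Within an answered week all
items must be present; missingness is whole-week.

## Eligibility

Participants need at least `min_weeks` (default 20, the conventional
threshold for intensive longitudinal data) non-missing weeks on every
modelled outcome, and — because a flat series carries no within-person
information — any modelled outcome with zero variance excludes the
participant.  Both rules are configurable and every exclusion is logged
with its reason.

## Synthetic-data generator

The generator draws covariates (Bernoulli at prevalences 0.384 BD-II,
0.68 female, 0.40 age >= 55, 0.30 rapid cycling), person effects from the
between-person model (rejection sampling keeps persons stationary; the
redraw count is reported and >50% rejection is an error), an initial
deviation from each person's stationary distribution, and recurses the
model equations, optionally rounding and clipping to the instrument
ranges.  Missingness can be injected completely at random or with a
logistic dependence on the most recent observed score (missing at
random); the logistic intercept is calibrated so the marginal rate matches
the requested rate.

Calibrated defaults carry the cohort-level estimates for this population:
individual-mean levels 1.98 / 7.33 / 3.29 and variances 1.96 / 21.10 /
3.71 for (hypo)mania / depression / insomnia, inertias 0.40 / 0.47 / 0.36.
Quantities the cohort tables do not pin down are documented choices:
log-innovation means 0.4 / 2.2 / 0.8 (innovation variances of roughly
1.5 / 9 / 2.2 points^2, consistent with the published within-person
variability of these scales), random-effect SDs 0.15 for all lag-matrix
entries and 0.5 for log innovation variances, trend mean -0.005
points/week with SD 0.005, and raw cross-lag means consistent with the
reported average standardised cross-lags at the calibrated scales
(e.g. 0.047 for insomnia-to-depression, 0.031 for
depression-to-insomnia).  Random-effect correlations default to zero and
are planted explicitly where a study condition requires one.  Covariate
prevalences for age and rapid cycling are plausible defaults, not
reported values.

For standardisation studies, `calibrate_cross_lag` adjusts one raw
cross-lag fixed effect by root finding (common random numbers across
candidate values) until the generator's implied average individually
standardised effect — a Monte-Carlo average over the random-effect
distribution — hits a requested value.

What the generator does *not* emulate: real adherence patterns (missing
weeks are MCAR/MAR by construction), ordinal item-level measurement
(scores are conditionally Gaussian; the discretise flag adds rounding,
which slightly attenuates dynamics), medication effects, or
non-stationary symptom regimes.  Passing recovery tests therefore show
the estimation machinery is correct under the model's own assumptions,
not that the model is correct for any particular cohort.

## Run sizes and numerical choices

Recovery studies use N = 300 participants and T = 91 weeks — full study
scale for the panel length, roughly half the cohort size — with 2 chains
of 2,000 + 2,000 iterations for univariate fits and 1,500 + 1,500 for
bivariate fits; at these sizes a univariate fit takes ~15 s and a
bivariate fit ~70 s on one CPU, and fixed-effect posteriors are stable to
~0.005 across chain seeds.  Lyapunov solutions are accepted at residuals
below 1e-10; person lag matrices are declared non-stationary at spectral
radius >= 1; near-singular precision matrices receive 1e-12 jitter before
factorisation.  At the calibrated heterogeneity (SD 0.15 on lag entries)
the N = 300 across-person average of standardised cross-lags itself has a
sampling standard error of ~0.017, so studies targeting that average pin
the simulated cohort with a fixed generator seed and vary only the
sampler seed.

## Known limitations

* One-week lag only; processes operating on other timescales are aliased.
* Two processes maximum (the analyses this supports are uni/bivariate).
* Diagonal innovation covariance; a within-week residual correlation
  between processes would be absorbed into the cross-lags.
* The initial-condition prior is empirical-Bayes rather than the person's
  own stationary distribution; the difference is O(1/T) and negligible at
  T ~ 90, but matters in principle for very short panels.
* Gaussian observations; heavy discretisation (e.g. the 0–9 insomnia
  scale near its floor) mildly attenuates estimated dynamics.
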