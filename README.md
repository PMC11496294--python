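# dmtpower

Power simulation for Parkinson's disease-modifying therapy (DMT) trials that
compare in-clinic MDS-UPDRS part III assessments with frequent digital
at-home measures (e.g. step length from a smartphone walk test).

Detecting a DMT effect means detecting a *change in the rate* of motor
decline, which is obscured by three distinct noise sources: measurement
error, short-term symptom fluctuation, and genuine variability in the
progression process itself. `dmtpower` simulates all three and asks how the
schedule of assessments — quarterly clinic visits, bursts of at-home
assessments, or evenly spaced at-home assessments — changes the sample size
a trial needs.

## The model

Latent disease severity θ follows a Gaussian random walk with drift. For
participant *i* with assessments at times *t* (years),

- θ(0) ~ N(μ_s, σ_s²)
- θ(t+Δt) = θ(t) + w,  w ~ N(e·τ·Δt, σ_T²·Δt)
- y(t) = θ(t) + v,  v ~ N(0, σ_m²)

τ is the annual progression rate, σ_T the SD of the trend accumulated over a
year, σ_m the single-assessment measurement error, and e ∈ (0, 1] the
treatment effect (e = 0.7 is a 30% slowing of progression; τ is the only
parameter differing between arms). Digital measures inherit τ and σ_T from
the clinic instrument rescaled by the ratio of measure means, optionally
shrunk by a responsiveness factor r.

Simulated trials are analyzed with a linear mixed model

    y ~ time * arm, random intercept per participant, AR(1) residuals

fit by maximum likelihood (implemented in `dmtpower.lmm`, cross-checked
against R `nlme::lme`), and the treatment effect is the t-test on the
time-by-arm interaction. Statistical power, type-I error, MDC-gated success
rates and required sample sizes are Monte-Carlo estimates over many
simulated trials.

A separate reliability module estimates test-retest reliability from
longitudinal at-home data via a random-intercept model with participant and
participant-by-fortnight effects: ICC, standard error of measurement σ_m,
and minimum detectable change MDC = 1.96·√2·σ_m, for individual assessments
or per-burst medians.

## Worked example

```python
from dataclasses import replace
import dmtpower as dp

# 1-year trial, 48 weekly at-home step-length assessments plus baseline
design = dp.make_design("even", duration_years=1.0)
params = dp.STEP_LENGTH_PARAMS           # tau=0.07/yr, sigma_T=0.15, sigma_m=0.06

trial = dp.simulate_trial(design, replace(params, effect=0.5), n_per_arm=110, seed=1)
fit = dp.fit_lmm(trial.records)
print(f"rate difference {fit.beta[3]:+.4f} m/yr, p = {fit.p_interaction:.4f}")

res = dp.estimate_power(design, params, effect=0.5, n_per_arm=110,
                        n_reps=200, seed=1)
print(f"power {res.power:.2f} +/- {res.mc_se:.3f}")
```

prints

```
rate difference -0.0363 m/yr, p = 0.0002
power 0.77 +/- 0.030
```

The fitted interaction (−0.036 m/yr) is the estimated slowing of step-length
decline in the treated arm — close to the simulated truth
0.5·0.07 = 0.035 m/yr — and a 110-per-arm trial with weekly at-home
assessments has roughly 80% power to detect a 50% slowing within one
year. The same question for quarterly clinic visits
(`dp.make_design("clinic_quarterly", 1.0)` with `dp.MDS_UPDRS_PARAMS`)
needs several times more participants.

A CLI wraps the pipeline for shell use:

```sh
dmtpower cohort --out cohort.csv --seed 1
dmtpower reliability --input cohort.csv --mode burst
dmtpower simulate --design even --years 1 --effect 0.7 --n-per-arm 100 --seed 1 --out trial.csv
dmtpower fit --input trial.csv
dmtpower samplesize --design even --years 2 --effect 0.7
```

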