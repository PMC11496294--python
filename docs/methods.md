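# Methods

## Progression and measurement model

Disease severity is latent and evolves as a Gaussian random walk with drift.
For a participant assessed at times t₀ < t₁ < … (years from baseline):

- θ(t₀) ~ N(μ_s, σ_s²), plus drift accumulated from 0 when t₀ > 0;
- θ(t_k) = θ(t_{k−1}) + w_k with w_k ~ N(e·r·τ·Δt, σ_T²·Δt), Δt = t_k − t_{k−1};
- y(t_k) = θ(t_k) + v_k with v_k ~ N(0, σ_m²).

The original model statement is a per-step update at the observed
timepoints; schedules here have unequal gaps (a day within a burst, weeks or
months between visits), so a rule for Δt is needed. We use increments with
mean τ·Δt and variance σ_T²·Δt — the unique embedding of a Gaussian random
walk in continuous time for which variance accumulates linearly, so the
annualized parameters mean the same thing under every schedule. The marginal
law implied, and verified by moment tests, is
y(t) ~ N(μ_s + e·r·τ·t, σ_s² + σ_T²·t + σ_m²).

The treatment effect e ∈ (0, 1] multiplies τ in the treated arm only (e =
0.7 is a 30% slowing); it is the single parameter differing between arms.
Progression is simulated as increasing severity; a measure that declines
(step length) is the mirror image and every power result is sign-invariant.

### Parameters

Clinic MDS-UPDRS part III: τ = 2.63/yr, σ_T = 5.58/√yr, σ_m = 3.94. The
13%/yr gloss on τ pins the baseline mean near μ_s = 20.2; σ_s = 9 is a
typical early-PD between-patient spread. μ_s and σ_s enter only the random
intercept, which the analysis model absorbs, so slope power is insensitive
to them.

Digital step length (meters): σ_m = 0.06 from at-home data; σ_T = 0.15. The
published trend range 0.04–0.07 (8%–13%/yr) brackets responsiveness: its
upper end is the full-responsiveness trend, 13%/yr, giving τ = 0.07 and
μ_s = 0.538 m — with which the rescaling rule below reproduces the printed
σ_T (5.58·0.538/20.2 = 0.149) and the lower end 0.04 ≈ 8%/yr corresponds to
r = 0.6. σ_s = 0.1 m.

Rescaling: latent progression is assumed instrument-independent up to units,
so τ_digital = τ_clinic·(μ_digital/μ_clinic) and likewise σ_T. A
responsiveness factor r ∈ (0, 1] further shrinks τ only — a digital measure
may track the underlying process more weakly without being noisier — while
σ_m is a property of the instrument and is never rescaled.

## Study designs

All schedules include a baseline assessment at t = 0 (a slope model needs
one; quarterly over 1 year = 5 visits, 2 years = 9 visits). The evenly
spaced design has n_per_year·duration + 1 assessments. Burst designs place
n_bursts evenly spaced anchors (first at t = 0) and fill each burst with
daily consecutive assessments (6 per burst spans 5 days, inside the 7-day
window that defines a burst; variants with more than 8 per burst pack the
window at spacing 7/(k−1) days). Burst outcomes are the per-burst median,
timestamped at the burst midpoint — the at-home outcome studied empirically.

## Effect-detection model

Each simulated trial is analyzed with the linear mixed model

y_ij = β₀ + β₁·t_ij + β₂·arm_i + β₃·(t_ij·arm_i) + a_i + ε_ij

with a_i ~ N(0, σ_b²) and AR(1) within-participant residual correlation
corr(ε_ij, ε_ik) = φ^|j−k| over assessment order (matching the nlme corAR1
convention; a φ^Δt continuous-time variant is available but not default).
The AR(1) structure approximates the serial dependence a random walk
induces; it was the empirically AIC-preferred structure and is deliberately
*not* the data-generating covariance — the residual mismatch is the source
of the type-I inflation studied below.

Fitting is by maximum likelihood (REML optional); ML is the default because
AIC comparisons across correlation structures are a primary use. The
residual variance is profiled out analytically and the optimizer works on
(log γ, atanh φ), γ = σ_b²/σ², with a coarse start grid (φ ∈ {0, 0.3, 0.7})
followed by Nelder-Mead (tolerance 1e−9 on the log-likelihood). Participants
sharing a schedule and arm share one covariance block, so balanced designs
cost one m×m Cholesky per likelihood evaluation regardless of n. In
Monte-Carlo loops each replicate warm-starts from the previous optimum. The
blocked likelihood is tested to 1e−8 against a dense-matrix oracle, and the
full fit against R nlme::lme (β, φ, log-likelihood, df, p).

The treatment test is the two-sided t-test on β₃ with between-within
denominator df = N_obs − N_participants − 2 (time and time×arm vary within
participant), the nlme rule. Degenerate noise-free data short-circuits to
the interpolating fit with variances at the zero boundary.

## Power, type-I error, MDC gating, sample size

Power = proportion of replicates with p(β₃) < α (default 0.05); each
replicate gets an independent child seed from one master SeedSequence, and
non-converged fits are excluded but counted. Monte-Carlo SE is
√(p(1−p)/reps). Under the null (e = 1) the same estimator gives empirical
type-I error: inflated above α for frequent schedules because the fitted
covariance understates the long-run variance of a random walk. The MDC-gated
success criterion additionally requires |β₃|·duration (estimated between-arm
difference in total change) to exceed the measure's MDC = 1.96·√2·σ_m;
gated power is ≤ ungated power by construction.

Sample-size search evaluates power on an ascending n-grid (200 replicates
per point in the shipped protocol, versus 1,000 in the full-scale study),
applies isotonic regression to the power-vs-n points, and returns the
smallest grid n whose smoothed power reaches the 80% target. Per-point seeds
depend only on (master seed, grid index), so the early-stop rule (halt after
two consecutive raw estimates clear the target) cannot change any computed
number. Grid steps of 30–120 participants set the resolution of the answer;
the published values are themselves "approximately" figures.

Scenario grids reuse one replicate seed stream across designs within a cell
(common random numbers) to sharpen design contrasts; absolute power
estimates use independent streams.

## Reliability of at-home measures

For longitudinal at-home data the variance decomposition
y_{i,f,k} = μ + a_i + b_{i,f} + ε (participant, participant-by-fortnight,
residual; fortnight = floor(days/14) from each participant's enrollment) is
estimated by REML via statsmodels MixedLM, with a closed-form guard for
noise-free data where the solver degenerates. ICC =
(σ_p² + σ_pf²)/(σ_p² + σ_pf² + σ_m²); SEM = σ_m; MDC = 1.96·√2·σ_m. Burst
reliability applies the same model to 7-day-window medians. Because the
model uses all assessments, arbitrary missingness is tolerated.

## Synthetic cohorts

The cohort generator emulates a 44-participant, 6-month daily-assessment
at-home study: Gaussian components at chosen (σ_p, σ_pf, σ_m), one
missing-completely-at-random adherence rate (default 34%, reproducing the
observed ≈4.6 assessments per weekly burst), values around μ = 0.5 m. It
does not emulate: measure-specific adherence, learning effects, progression
within the cohort window, heavy-tailed or heteroscedastic noise, or
informative missingness. Passing recovery tests therefore show estimator
correctness under the stated model, not robustness to those features of real
data.

## Scaled-down protocol and numerical choices

Shipped tests and the acceptance script run 200 replicates per power
estimate (1,000 for the type-I study, matching the full-scale count), chosen
so the whole suite completes on a single CPU in minutes while keeping
Monte-Carlo SE near 0.03 on a power of 0.8. Variances are constrained
nonnegative by log/atanh parameterization; |φ| is capped at 0.999;
optimizer failures raise with diagnostics rather than returning silently.

## Known limitations

- Mean progression is linear in time; learning effects, symptomatic-therapy
  transitions (e.g. starting levodopa), time-varying treatment effects and
  subpopulations with distinct rates are out of scope.
- Required sample sizes from this pipeline run some 15–20% above the
  published approximate values across all designs, while every ordering and
  between-design ratio reproduces; the analysis machinery itself matches
  closed-form power where theory exists, so the offset traces to
  protocol details of the original simulations (per-step noise scaling
  across unequal gaps, sample-size read-out) that are not fully specified.
- Satterthwaite/Kenward-Roger df, random slopes and general covariance
  structures are not implemented; the between-within df rule is adequate at
  trial-scale N.
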