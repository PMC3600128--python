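# Methods

## The stop signal task and the race model

The simulated task mirrors the standard community-testing protocol: a
24-trial practice block (18 go, 6 stop) followed by four experimental
blocks of 24 trials — 72 go and 24 stop trials — with the stop signal on a
random 25 % of trials per block and 3,000 ms allowed for a response.

Trial outcomes follow the independent horse-race model. Each trial draws a
go-process finish time; stop trials additionally draw a stop-process finish
time at `SSD + SSRT_draw`. The response is emitted iff the go process wins
(and finishes inside the response window), subject to an omission
probability. The stop-signal delay starts at 250 ms and moves ±50 ms by a
one-up/one-down staircase — up after a successful stop, down after a failed
one — which converges on the delay where inhibition succeeds half the time.
The delay is floored at 0 ms (a negative delay is physically meaningless);
the floor is a parameter.

Distributional choices (the task literature's standard stand-ins; they are
configuration, not claims about any particular dataset):

- **Go finish times** are ex-Gaussian, `mu + sigma·N(0,1) + Exp(tau)`.
  Defaults `mu=469, sigma=92, tau=130` give a go-RT mean of 599 ms and SD
  of 159 ms, typical of 6–18-year-old community samples.
- **Stop latencies** are normal truncated at zero (`ssrt_mean=280`,
  `ssrt_sd=60` by default).
- A go trial with no response inside the window is an **omission**, counted
  as inaccurate by the accuracy filter — a conservative choice so quitting
  or inattention is caught by the validity screen.
- The practice block is simulated (so the experimental portion starts from
  a partially adapted delay, as in live testing) but excluded from scoring.

## Scoring and validity

Per participant, over experimental trials only: go accuracy (correct
responses / all go trials, omissions counting against), GoRT mean and
sample SD over responded-and-correct go trials, probability of inhibition,
mean SSD over presented stop trials, and the integration SSRT. The
integration estimator ranks the responded no-signal RTs ascending, takes
the RT at rank `ceil((1 − p_inhibit)·n)` — the faster `1 − p(inhibit)`
fraction of go responses would have escaped inhibition, all slower ones
would have been stopped — and subtracts the mean delay. All responded go
RTs enter the ranking (including choice errors), matching the estimator's
definition over no-signal trials; failed-stop RTs never do. At
`p(inhibit) = 0.5` the estimator reduces to the classical
`mean GoRT − mean SSD` subtraction. It is undefined at p(inhibit) of 0
or 1; such sessions fail the inhibition filter anyway.

Validity filters: go accuracy ≥ 0.66, GoRT ≥ 100 ms (guessing screen),
p(inhibit) within [0.20, 0.80] (strict sensitivity mode: [0.40, 0.60], the
95 % band around the staircase target), and a completeness flag for
truncated sessions. Thresholds are inclusive; relaxing any threshold can
only add valid participants.

Stimulant medication shortens SSRT by roughly 0.75 standard deviations at
moderate doses, so the correction for medicated participants **adds**
`0.75 × SD` to estimate the untreated value, anchored on the SD among
unmedicated valid participants (a published clinical SD could be
substituted via the `reference_sd` argument). The primary analysis path
excludes medicated participants; the correction is the sensitivity path.

## Trait regressions

Log-transformed SSRT / GoRT / GoRTSD are regressed on sex, reversed SWAN
trait score and age with a family-level random intercept (statsmodels
`MixedLM`, ML). The natural log is used; the base affects only coefficient
scale. Terms enter by forward stepwise selection at Wald `entry_alpha =
0.05` (no criterion is standard; 0.05 is the conventional default), and
the higher-order terms age², age×sex and age²×sex are assessed only once
all main effects are in. Models of GoRTSD can force GoRT in as a control
covariate rather than modelling the ill-behaved GoRTSD/GoRT ratio.
Stepwise selection depends only on fitted statistics, so it is invariant
to row order. When the family variance collapses to the zero boundary the
mixed-model information matrix is singular; the fit then falls back
through alternative optimizers and, in the degenerate limit, to the
boundary-equivalent fixed-effects solution.

Prediction grids evaluate the fixed effects at covariate extremes (random
effect at zero) and back-transform by plain exponentiation — the predicted
median, with no smearing correction. Intervals come from the
linear-predictor standard error; the SD of a single new observation
combines prediction, family and residual variance on the log scale and is
mapped to ms by the delta method.

Two effect-size modes exist. The **pooled** default is Cohen's d with
`sqrt((sd1² + sd2²)/2)` in the denominator, treating the cell SDs as
single-observation SDs. A **printed** mode retains, for fidelity, the
as-printed approximation with the *difference* of squared SDs under the
root; it is near-degenerate whenever two cells have similar dispersion and
raises rather than silently correcting. The sign under the root is treated
as a typographical issue: both behaviours are available, neither is
patched.

A reference predicted-value grid (SSRT/GoRT/GoRTSD by sex, age 6/18, trait
−54/+54, in `stoprace.reference`) supports worked-example contrasts — e.g.
the 138 ms SSRT difference between trait extremes for girls at age 6 — and
anchors the synthetic generator's calibration.

## Variance components

Within a family, the phenotype vector (after the covariate mean model,
estimated simultaneously by GLS, never residualized in a prior pass) is
multivariate normal with covariance `σ²_A·K + σ²_E·I`, where `K` has 1 on
the diagonal and ½ between full siblings. Because `K` is compound
symmetric, the correlation matrix at a given h² is
`(1 − h²/2)·I + (h²/2)·J`, whose inverse and determinant are closed-form
per family size; the likelihood profiles over β (GLS) and the total
variance (closed form), leaving a one-dimensional optimization over
h² ∈ [0, 1] (grid bracket + bounded refinement). Standard errors come from
the observed information in (h², σ²_P); the h² = 0 test uses the
likelihood-ratio statistic with the ½χ²₀ + ½χ²₁ boundary mixture. The
asymptotic CI is `h² ± Z(α/2)·SE`, clamped to [0, 1]. Singleton families
are retained — they inform the mean model and total variance though they
carry no kinship signal; a pedigree of only singletons is unidentifiable
and raises.

The bivariate model stacks both traits per family: cross-trait covariance
`ρ_g·σ_A1·σ_A2 + ρ_e·σ_E1·σ_E2` within person and `½·ρ_g·σ_A1·σ_A2`
between siblings. Six parameters (two heritabilities, two log total
variances, ρ_g, ρ_e) are optimized by bounded L-BFGS-B from three starts
(phenotypic-correlation and ±0.9 genetic-correlation seeds) with both mean
vectors profiled by joint GLS; the ρ_g = 0 test is a χ²₁ LRT (an interior,
two-sided parameter, unlike the variance boundary), and the reported
phenotypic correlation satisfies
`ρ_P = ρ_g·√(h₁²h₂²) + ρ_e·√((1−h₁²)(1−h₂²))` by construction. Estimates
with |ρ_g| at the bound are flagged `boundary` and their SE is not
reported. A trait whose h² sits at the zero boundary makes ρ_g
unidentifiable and raises.

No household/shared-environment component is fitted: with sibling-only
pedigrees it is confounded with additive variance, and the familial
correlation is interpreted as genetic, consistent with twin evidence that
shared-environment effects on these measures are minimal. h² here is
therefore an upper-bound-style "broad familial" estimate under that
assumption.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs:

- **Families**: sizes 2–5 drawn with weights 3081 : 387 : 35 : 4 (≈ 2.13
  children per family, so 3,507 families ≈ 7,480 children), ages uniform
  6–18, 49.9 % male.
- **Latent traits**: per trait, `sqrt(h²)·g + sqrt(1−h²)·e` with the
  genetic value `g` built from a family factor and an individual factor
  weighted `√0.5` each — sibling genetic correlation exactly 0.5 — and
  cross-trait structure from ρ_g/ρ_e matrices (validated for positive
  semi-definiteness; an invalid matrix raises naming the offending pair).
  Default h²: ADHD 0.38, SSRT 0.31, GoRT 0.26, GoRTSD 0.28.
- **SWAN-style scores**: 18 items, each a discretized shifted normal
  clipped to the 7-point scale (the simplest item model honoring the
  bounded scale), summed to inattention and hyperactivity-impulsivity
  subscales of 9 items and a total that equals their sum by construction.
  Emitted directly on the reversed analysis scale (+54 = maximal ADHD
  traits) with population mean −5.8 and SD 16.3, the item scale chosen so
  the total SD includes item noise. Boys score ~3 points higher by
  default.
- **Trait → race parameters**: log-linear maps calibrated against the
  reference grid — SSRT rising ≈ 138 ms and GoRTSD ≈ 51 ms from trait −54
  to +54 at age 6, both gradients shrinking multiplicatively with age, a
  small male advantage vanishing by 18. Latent task-trait residuals flow
  in through per-channel loadings (SSRT 0.30, GoRT 0.12, GoRTSD 0.20 on
  the log scale) plus idiosyncratic noise, so measured task phenotypes
  carry both the SWAN-mediated and the trait-specific heritable signal.
  Go parameters derive from target mean/SD as `tau = 0.8·SD`,
  `sigma = 0.6·SD` (so `sqrt(sigma²+tau²) = SD`), `mu = mean − tau`.
- **Medication** (2.6 %, odds rising with trait): simulated with
  multiplicatively shortened stop latencies (0.75 × the typical log-SSRT
  dispersion), so the scoring-side correction path is exercisable.
- **Invalid performers** (5 % by default, skewed younger / higher-trait /
  male): guessers (fast random responding), erratic responders (errors and
  omissions), and quitters (sessions truncated at 30–70 experimental
  trials), so the exclusion accounting reproduces the real-world pattern
  that excluded cases have higher traits and are younger males.

What the generator does **not** emulate: non-sibling relatives, assortative
mating, shared-environment effects, SWAN distribution shape beyond its
first two moments, item-level response styles, RT autocorrelation or
fatigue within a session, and context effects after stop trials. Passing
recovery tests therefore demonstrates the estimators' correctness under
the stated additive model, not robustness to these real-data features.

## Problem sizes and numerics

Test and acceptance problem sizes are chosen to hold Monte-Carlo error
well below the asserted tolerances: 2,000 participants for staircase
tracking (binomial SE of the grand mean ≈ 0.001), 10,000 for SSRT
recovery (SE ≈ 0.5 ms against a 15 ms band; residual bias of a few ms
stems from the finite 24-stop-trial sessions and the discrete staircase),
3,507 families for heritability recovery (SE ≈ 0.03, matching the
precision a real cohort of that size supports), and 6-member toy
pedigrees for the dense grid-search likelihood oracle (2,001-point grid,
agreement to 3 decimals). The one-dimensional h² profile is optimized to
1e−8; observed-information steps are 1e−4 with the stencil kept inside
the parameter space near boundaries, where SEs are reported as undefined
rather than extrapolated.

## Known limitations

- Heritability SEs and LRT p-values are asymptotic; at a few hundred
  families the normal approximation for h² is rough near 0.
- The bivariate optimizer can, rarely, prefer an interior ρ_g when the
  truth is at the boundary in small samples; multi-start reduces but does
  not eliminate this.
- The medication correction assumes a uniform treatment effect; the
  generator implements the same assumption, so this path validates
  plumbing, not the clinical estimate.
- Measured-phenotype heritability from the full simulate-and-score
  pipeline is attenuated below the configured latent h² by SSRT
  measurement noise (24 stop trials per child); recovery tests on latent
  traits are the calibration-free check of the estimator itself.
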