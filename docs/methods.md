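# Methods

## Model and state

The model is a one-dimensional forced decline. Cortical network
adaptability N(t) is dimensionless on [0, 1] (N₀ = 1 by default; the
framework never fixes a scale, but the 0.3 entrapment threshold presumes a
unit-like one). Time is measured in weeks, matching the weekly/monthly
assessment schedules the framework envisages. Two nonnegative inputs force
the decline: reflex-circuit injury I(t) and cortical injury load C_I(t),
supplied as parametric time courses (constant, exponential decay with time
constant τ, or piecewise constant). The decline rate is

    dN/dt = −η · (behavioral_load(t) + gain_collapse(t)),

with both components linear in (I, C_I) given the twelve coupling
coefficients. The right-hand side does not involve N, so
N(t) = N₀ − η ∫₀ᵗ load(s) ds, clamped to [N_floor, N₀] (floor 0).

**Collapse conventions.** The printed gain-collapse bracket equals ψ·G₀ at
zero injury, i.e. the uninjured brain decays linearly forever; the prose
describes the same term as the *shortfall* between the reserve G₀ and the
degraded capacity, which vanishes at zero injury. Both are implemented;
`shortfall` is the default because it yields a no-injury fixed point and a
load that is always nonnegative. The `literal` convention is retained for
fidelity tests and can drive dN/dt positive when receptor support exceeds
the degradations; in that regime clamping is applied stepwise so decline
restarts from the clamp.

**Receptor extension.** H(t) = max{0, G₀ + ζ·R_net(t)},
R_net = R₀ + R_stim(t) + R_loss(t) (R_loss ≤ 0). Under the literal
convention H(t) substitutes for G₀. Under the shortfall convention —
where G₀ does not appear — stimulation enters as a relief term
max{0, ζ·R_stim(t)} subtracted inside the bracket, floored at zero. ζ
defaults to 0.5 (no published range exists for it). The extension is
isolated behind an `enabled` flag and off by default.

**Quadrature.** Each signal family has a closed-form integral, and the
load is affine in the signals, so the cumulative load is computed exactly
at the grid points (step 0.1 week); no ODE solver is involved. Trapezoidal
quadrature is used only when the receptor extension introduces
time-varying max(0, ·) terms. Entrapment is N(t) < threshold (default 0.3,
strict); the crossing time is linearly interpolated between bracketing grid
points, and touching the threshold exactly does not count.

## Priors

Each coefficient has a published plausible range inside (0, 1). Its prior
is the Beta distribution with mean at the range midpoint and standard
deviation (hi − lo)/4, so the range carries ≈95% of the mass under a normal
approximation; shapes come from moment matching
(concentration = m(1−m)/v − 1). α is the exception: its worked example
pins the mean at 0.5 rather than its midpoint 0.55. "Centered on the
range" could also mean mode-centered; midpoint was chosen and applied
uniformly. Priors live on (0, 1) directly since every range already does.
G₀ is fixed at 1 unless a G₀ prior is supplied; there are no hierarchical
hyperpriors (estimation is patient-level).

## Observation model

The framework predicts near-exponential symptom decay in recovering
patients, but N itself is monotone non-increasing, so symptoms cannot track
1 − N alone. Scores on a generic 0–100 scale (the clinical instrument
prints no scale) mix the instantaneous total load, normalized by its value
at injury (weight 0.8 — this term decays with the injury input and
realizes the exponential recovery), and the accumulated adaptability loss
1 − N(t) (weight 0.2). Entrapped patients carry an additional persistent
floor of 10 points. Observation noise is i.i.d. Gaussian with variance
noise_fraction/(1 − noise_fraction) × Var(noiseless scores), so noise
contributes noise_fraction (default 0.2) of the total score variance;
scores are clipped to [0, 100].

A consequence worth stating: because the noise sd is tied to whole-
trajectory variance (dominated by the large early scores), late-window
readings carry sd ≈ 8–11 points even in near-recovered patients. Two
design choices below respond to this.

**Persistence at three months** is judged on sustained late symptoms: the
mean of all assessments at weeks ≥ 12 must exceed 15 points. A
single-reading week-13 criterion under the noise model above misclassifies
~10% of fully recovered patients as persistent, which would make the
3-fold/4-fold biomarker risk targets unreachable by any mechanistic
calibration; averaging the four late assessments drops that rate to ~1–3%.
**Recovery time** is the first week of two consecutive assessments below 15
(censored at the last assessment).

## Synthetic cohort and risk calibration

Each patient draws a true coefficient vector from the priors and an injury
class: *mild* (I₀ ∈ [0.4, 1.2], C_I₀ ∈ [0.1, 0.5]) or *severe*
(I₀ ∈ [8, 12], C_I₀ ∈ [3, 5]), both exponential-decay courses with
τ_I ∈ [2, 3.5] and τ_CI ∈ [2.5, 4.5] weeks. Effective magnitudes are
multiplied by exp(0.35·z_α + 0.20·z_ρ − 0.35·z_η) (z standardized against
the priors, capped to [0.4, 3]): vulnerable reflex profiles sustain larger
effective loads. The η term follows the framework's recovery-phenotype
reading of η as reserve (low η ⇒ slow recovery) even though η multiplies
the decline rate in the equation itself — the two readings conflict, and
without this coupling the slow phenotype (high α, low η) would *not* have
worse outcomes than the fast phenotype (low ρ, high η).

Baseline biomarkers define exposure strata: VOR asymmetry > 20%
(prevalence 0.25, exposure probability tilted by α), primitive-reflex
count ≥ 2 (prevalence 0.20, tilted by ρ), SOT composite < 60
(prevalence 0.12). Stratum risks of three-month persistence are additive,
r(x_vor, x_reflex) = r₀ + d₁x_vor + d₂x_reflex with base rate r₀ = 0.06,
and (d₁, d₂) solve the two marginal risk-ratio constraints (targets 3 and
4) exactly under independent exposures. A multiplicative model cannot work
here: 3 × 4 would saturate the jointly-exposed stratum.

The only dial connecting strata to outcomes is the severe-class probability
p_sev(stratum). It is solved from
r_target = p_sev·a + (1 − p_sev)·b, where a and b — the class-conditional
persistence probabilities — are estimated by an internal pilot simulation
(default 12,000 patients, each simulated under both classes) *per stratum*,
so the biomarker–parameter coupling introduces no bias. Infeasible targets
(saturated base rate, non-separating classes) raise a configuration error
rather than being silently clipped. Abnormal-SOT probabilities per injury
class are solved the same way from pilot mean-burden estimates to approach
the 2-fold burden-ratio target (under the defaults the mild-class
probability clips at zero and the realized ratio is just under 2). No
outcome labels are ever flipped post hoc; the chain biomarker → parameters
→ injury → dynamics → noisy scores → outcome stays intact.

**Trials.** The two-arm trial population draws slower-resolving injuries
(τ_I ∈ [5, 9] weeks, I₀ ∈ [1, 4]), mimicking a persistent-symptom
population. The intervention multiplies both injury decay *rates*; the
multiplier is calibrated by bisection on a paired pilot (the same pilot
patients and noise streams under both arms, cancelling patient-level
variance) so the expected percent advantage in mean baseline-to-week-12
symptom reduction equals the 40% target. Randomization, assignment and all
draws are deterministic given the seed.

**What the generator does not emulate:** dropout and missing assessments,
instrument-specific score distributions, between-site heterogeneity,
comorbidity structure, placebo response, or any neuroimaging outcome.
Passing tests therefore show that the estimation and validation machinery
behaves correctly *when the model is true*, not that the model describes
real patients.

## Inference

The likelihood is Gaussian: observed scores around the noiseless predicted
scores of a candidate coefficient vector, with noise sd estimated as
sqrt(noise_fraction × Var(observed scores)) unless supplied. Coefficients
enter the dynamics only through products (γα, λμ, …), so the full
twelve-coefficient vector is unidentifiable from one scalar trajectory; the
default fit frees {α, η, ρ} and fixes the rest at prior means (the priors
regularize larger free sets if requested).

Sampling is random-walk Metropolis in the logit of the free coefficients
(the Beta prior density picks up the expit Jacobian), four chains by
default, 50% burn-in, per-chain proposal scale adapted every 100 burn-in
iterations toward 20–40% acceptance and frozen afterwards. Chains are
independently seeded from a single spawning seed. Convergence is judged by
split Gelman–Rubin R̂ (each chain halved; accept below 1.1); effective
sample sizes come from ArviZ. Credible intervals are equal-tailed pooled
quantiles. Posterior predictive checks report the pointwise coverage of
the observations by the predictive interval over replicated datasets.
AIC/BIC use the best posterior draw as the maximum-likelihood proxy, which
slightly understates the maximum; k is the number of free parameters and n
the number of assessments.

## Sensitivity

Local sensitivities are central finite differences (step 1e−4, one-sided at
the unit-interval boundary) of final N, entrapment crossing time, or
integrated load; for parameters that enter the load linearly these match
the analytic derivatives to ~1e−6. Global first-order indices use the
binned correlation-ratio estimator over prior draws (20 equal-count bins,
Var of conditional means over Var of output, clipped to [0, 1]) — adequate
for a cheap scalar model and swappable behind the same interface; total-
order indices are not computed. Crossing times are censored at the horizon
for the global analysis; a (near-)constant output returns all-zero indices
with a degenerate-output flag.

## Validation

Train/test splits are chronological within patient (first ⌈0.7n⌉
assessments train, the rest test): patient-specific coefficients cannot
predict unfitted patients without a population model, so the forecasting
orientation is the meaningful one. Pooled R² is 1 − SSE/SST over all test
points with SST about the pooled mean; RMSE is in score units. Because the
test window is the low-variance late tail while the noise sd is set by
whole-trajectory variance, out-of-sample R² has a noise-imposed ceiling
well below the in-sample value — forecasts on well-specified data clear the
0.3 falsification guard by a wide margin, while the 0.6 level is
approached but remains sensitive to cohort composition. Risk ratios use
the log-normal confidence interval with a 0.5 continuity correction on zero
cells (flagged). AUC is the tie-adjusted rank statistic; the default
parameter-based stratification score is α·(1 − η), the slow-recovery
profile direction.

## Problem sizes and determinism

Desk-scale defaults used by the test suite and the acceptance script: risk
ratios from 20,000-patient cohorts (12,000-patient calibration pilot);
variance explained from 50 patients fitted with 3 chains × 1,200
iterations; convergence and the worked example at 4 chains × 5,000;
recovery studies at 50 replicates; trials at up to 2,000 per arm with a
2,000–3,000-patient paired calibration pilot. Every stochastic stage
derives its stream from one seed via spawned seed sequences, so all
reported numbers are exactly reproducible.

## Known limitations

- The twelve coefficients are structurally non-identifiable from a single
  symptom trajectory; only low-dimensional subsets are estimated, and
  fixed-coefficient misspecification is absorbed by the free ones.
- The symptom mapping and all base rates (persistence, exposure
  prevalences) are package choices; the framework prints none.
- WAIC/LOO-CV, Bayes factors, hierarchical population models, nonlinear
  mixed-effects fitting, dropout processes and neuroimaging endpoints are
  out of scope.
- The literal-convention receptor path uses sampled (trapezoidal)
  quadrature and stepwise clamping; its accuracy is O(step²) rather than
  exact.
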