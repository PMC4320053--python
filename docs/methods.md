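# Methods

## Model

The observer infers whether four noisy sensory cues — visual and
proprioceptive hand positions (χᵥ, χₚ; mm along the azimuth, midline at 0)
and visual and tactile stroke timings (τᵥ, τₜ; ms within the trial, 0 at
trial start) — share one environmental cause or arise from two.  Cue noise
is Gaussian around the latent stimulus values, the spatial and temporal cue
pairs are statistically independent, and the latent position *X* and time
*T* carry Gaussian priors 𝒩(μ_X, σ_X) and 𝒩(μ_T, σ_T).

Both marginal likelihoods are analytic.  For one cue pair (a, b) with noise
SDs (s_a, s_b) and prior 𝒩(μ₀, s₀), the common-cause marginal is a
bivariate Gaussian with log density

    −log 2π − ½ log D − [ (a−b)² s₀² + (a−μ₀)² s_b² + (b−μ₀)² s_a² ] / 2D,
    D = s_a² s_b² + s₀² (s_a² + s_b²),

and the independent-causes marginal is the product of 𝒩(μ₀, √(s_a²+s₀²))
and 𝒩(μ₀, √(s_b²+s₀²)) densities.  The full likelihoods are products of
the spatial and (when strokes are present) temporal factors.  The posterior
probability of a common cause is the logistic of the log likelihood-ratio
plus the log prior odds; at the cue discrepancies of interest (a 16 cm hand
separation is more than a 10-SD spatial conflict) the raw densities
underflow double precision, so every path runs in log space and the
posterior saturates exactly at 0/1 rather than dividing degenerate
quantities.

Under squared-error loss on the position and timing estimates the optimal
readout is the posterior mean — the mixture of the fused estimate (the
precision-weighted mean of both cues and the prior) and the per-modality
segregated estimates, weighted by the causal posterior (model averaging).
The implementation reports the averaged estimates together with both
components, so a maximum-a-posteriori-style readout of either causal
structure can also be inspected.

## Parameters and units

Canonical internal units are millimetres and milliseconds; configuration
files declare a unit per key ("0.1 cm", "0.75 s") and cm/m/s are converted
on load.  Defaults:

| parameter | value | meaning |
|---|---|---|
| σᵥ | 1 mm | visual spatial SD (visual acuity at ~40 cm viewing distance) |
| σₚ | 15 mm | proprioceptive spatial SD |
| σ_tv, σ_tt | 20 ms | visual and tactile temporal SDs (temporal JNDs) |
| p(C=1) | 0.5 | prior probability of a common cause |
| χᵥ, χₚ (true) | 160 mm, 320 mm | rubber / real hand azimuths |
| async offset | 750 ms | midpoint of the 0.5–1 s stroking lag range |
| μ_X, μ_T | 0 | prior means (midline; trial start) |
| σ_X, σ_T | calibrated (≈3.56·10⁴⁴) | wide prior widths, see below |

## Prior-width calibration

The priors over *X* and *T* are meant to approximate uniform distributions,
but the causal posterior depends on their widths through the Occam factor:
the independent-causes hypothesis pays the wide-prior penalty twice per
dimension, so widening the prior favors the common cause without bound.  An
improper flat prior is therefore ill-defined here (it drives p(C=1) → 1),
and "a large number" is not a complete specification.  We treat the width
as the model's single calibrated degree of freedom: a root search on
log σ_X (σ_T moved by the same log-factor, preserving the template ratio)
finds the width at which a noise-free synchronous trial at a 30 cm hand
separation — the separation at which the illusion is known to fade — sits
at posterior exactly 0.5.  With σₚ = 15 mm a 30 cm conflict is a 20-SD
event, so the calibrated width is astronomically large (σ_X = σ_T ≈
3.561·10⁴⁴); this is a statement about the likelihood-ratio scale, not a
physical length.  The arithmetic is exact in log space (σ² ≈ 10⁸⁹ is well
inside double range).

The calibration objective is *not* globally monotone in σ_X: a very narrow
prior also favors the common cause when both cues sit far from μ_X (one
improbable latent draw beats two).  The search brackets the wide-prior
branch (σ_X ∈ [10⁴, 10⁸⁰] mm), where the posterior is strictly increasing
in the width; an absent sign change raises a calibration error carrying the
objective curve.  The shipped default config records the calibrated values
with provenance, and a test re-derives them from scratch.

## Simulator

Each Monte Carlo trial draws cues around the true stimulus values with the
model's own likelihood SDs (χᵥ ~ 𝒩(160, σᵥ), χₚ ~ 𝒩(320, σₚ); τᵥ ~
𝒩(t₀, σ_tv), τₜ ~ 𝒩(t₀+Δ, σ_tt), with the stroke time t₀ = 1000 ms —
immaterial under the translation-invariant wide temporal prior, which a
test asserts), evaluates the model-averaged estimates, and counts the trial
as an illusion when p(C=1|cues) > 0.5.  The threshold is configurable.
Conditions: `sync` (Δ = 0), `async` (Δ = 750 ms by default, admissible
500–1000 ms), `no_stroke` (no temporal dimension at all; inference runs on
the spatial cues alone).  The distance sweep moves the rubber hand 16→36 cm
from the real hand in 2 cm steps with synchronous temporal input and
reports the smallest tabulated separation at which the illusion frequency
drops below one half, plus the linearly interpolated 0.5 crossing.  Cues
are sampled per trial (the reported frequency is a per-trial proportion),
not evaluated noise-free.  Default 100,000 trials per condition; the
routine test suite and the acceptance script use 10,000 per point, where
the binomial standard error (≤ 0.005) is negligible against the effects
measured, and wider Monte Carlo tolerances where relevant.  Randomness
derives from a single seed via `numpy` `SeedSequence` spawning, one child
stream per sweep point, so results are bit-reproducible and individual
points re-runnable.

## Experiment analyses

*Proprioceptive drift* is the mean post-test minus mean pre-test
localization (40 responses each), positive toward the rubber hand.
Subjects whose mean pre-test localization deviates more than 3 sample SDs
from the sample mean are excluded; the screen is one-pass (statistics
computed once on the full input), not iterated.  Per group: two-tailed
one-sample t against zero with Cohen's d = mean/SD; omnibus one-way ANOVA
over the four groups; planned one-tailed independent t of sync against each
control with pooled-SD Cohen's d; a paired t of the first vs last 15
post-test trials checks that drift does not dissipate.

*Ownership* ratings (integers −3…3) are treated as ordinal.  Pre-test
ratings pooled over the three rubber-hand groups (procedurally identical
before stimulation): fraction positive — "rated the rubber hand as their
own" is operationalised as rating > 0, since the scale anchors
disagree/agree around 0 — median, and an exact sign test (zeros dropped,
two-sided binomial).  Change scores (post − pre) are compared across groups
with Kruskal-Wallis; the planned pairwise comparisons are Mood's median
tests, the independent-samples analog of the sign test (a literal sign test
requires paired observations, which a between-groups design does not
supply).  Ownership–drift association is a Pearson correlation, computed
separately for pre- and post-test ratings.

*Skin conductance*: the event-related response is the maximum minus the
minimum conductance over samples in the closed window [event+1 s,
event+5 s] (both endpoint samples included), transformed as log₁₀(SCR+1);
the raw value is reported alongside and the window and log base are
configurable.  Per time-point (eye opening, threat): one-way ANOVA over the
three groups and planned two-tailed t-tests of the plausible-arm group
against each control with pooled-SD Cohen's d; ownership medians, positive
fractions and sign tests per rated group; Pearson correlations of ownership
with each time-point's transformed SCR over the two rated groups.

*Baseline bias*: true hand position minus mean pre-test localization
(positive toward the midline), one-sample t across subjects, plus the mean
of per-subject SDs of the pre-test responses.  If no true position is
recorded or supplied the result is explicitly unavailable.  The *normality
screen* reports, per test (Shapiro-Wilk, Anderson-Darling, Jarque-Bera,
Lilliefors), the fraction of subjects whose pre-test sample is not rejected
at α = 0.05; subjects with fewer than 8 responses or zero variance are
flagged and excluded from denominators.

Planned comparisons are reported unadjusted by default; `drift_inference`
and `exp2_inference` take a `holm=True` flag that attaches Holm-adjusted
p-values alongside.  All inferential machinery delegates to scipy.stats and
statsmodels.

## Synthetic cohorts

The generators produce per-subject tables in the same CSV dialects the
loaders read, bit-reproducibly per seed.  Experiment 1 (21 subjects/group):
subject localization mean = true position (320 mm) − baseline bias
(31.5 mm) + between-subject noise (SD 15 mm); 40 pre and 40 post draws with
within-subject SD 13 mm; post shifted by subject drift = group mean + noise
(SD 10 mm); group drift means 10/6/5/2.5 mm (sync/async/no-stroke/no-hand),
chosen so the one-sample effect sizes echo the magnitudes the pipeline is
meant to detect (d ≈ 1.0/0.6/0.5/0.25 at this drift SD).  Ownership is a
latent Gaussian — intercept 1.1 (−2.0 for the no-hand group) + 0.06/mm ×
drift + noise (SD 1.5) — discretized at half-integer cuts to −3…3, giving
pooled positive fractions near 0.73 and ownership–drift correlations in the
0.3–0.45 range.  Experiment 2 (17 subjects/group): 120 s traces at 10 Hz,
tonic level ~8 µS with a slow sinusoidal wander and 0.02 µS sample noise;
event-locked bumps (0.5 s linear rise, 2 s exponential decay, 1.2 s onset
latency — the shape is irrelevant to the max−min statistic beyond its
amplitude) at 30 s (eye opening) and 90 s (threat); amplitudes
𝒩(0.9, 0.3) µS for the plausible arm and 𝒩(0.25, 0.15) for both controls,
threat scaled by 0.85; ownership latent = group mean (1.8 / −2.8) +
standardized amplitude + noise (SD 0.8) for the two rated groups.

What the generators do *not* emulate: serial dependence and drift within a
localization block, non-Gaussian response tails, tonic SCR nonstationarity
beyond a sinusoid, habituation across events, and any coupling between
pre-test bias and subsequent drift.  Passing tests on synthetic cohorts
therefore demonstrate that the pipeline's statistics are calibrated and
recover injected effects under its own assumptions — not that real data
satisfy those assumptions.

## Numerical and testing choices

- Posterior computed as a logistic of log-odds, clipped at ±745 before
  exponentiation (saturates exactly at 0/1 past double range).
- p_common = 0 or 1 short-circuits to the forced posterior.
- Group drift vectors are sorted before inference so results are invariant
  to input row order at the floating-point level.
- CSVs are written with `%.17g` and read with round-trip float parsing, so
  generated cohorts survive the disk round trip bit-exactly.
- Degenerate inputs: a temporal-model evaluation without temporal cues is
  an error (spatial-only analysis must be requested explicitly); empty
  localization sequences, events outside the trace, all-excluded cohorts
  and zero-variance correlations raise instead of returning NaN.
- Test oracles: closed-form marginals are checked against adaptive
  quadrature of the defining integrals (relative tolerance 1e-8, 100+
  random draws in a moderate-width regime where quadrature converges); the
  quadrature supplies break points bracketing the narrow integrand peak so
  it cannot be stepped over.  Statistical calibration uses 1000 seeded null
  cohorts per experiment (type-I rates asserted in [0.03, 0.07] at
  α = 0.05); recovery checks assert near-nominal 95%-CI coverage across
  replicate cohorts rather than a single draw.

## Limitations

- The model addresses the standard illusion only: no hand-posture or
  appearance congruence variables, no movement/self-touch variants, and no
  temporal dynamics of illusion onset — p(C=1) is a per-trial quantity.
- Prior widths are calibrated to the known spatial extent of the illusion
  rather than measured independently; all downstream "predictions" of the
  spatial boundary inherit that choice (the no-stroke and asynchrony
  results do not depend on it qualitatively).
- The decision rule (illusion ⇔ p(C=1) > 0.5) is one reading of how a
  graded posterior becomes a binary report; the threshold is exposed.
- Mood's median test stands in for between-group "sign tests"; with n = 21
  per group its power is modest.
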