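# Methods

This note documents the models behind `mesocam`, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer should know about.

## Independent detections, effort, and RAI

A *detection event* starts whenever the gap to the previous photograph of the
same species at the same station strictly exceeds `gap_minutes` (default 30;
a gap of exactly 30 minutes continues the event).  Multiple individuals in
one frame are a single detection, and photos with identical timestamps are
collapsed before the gap rule runs.  Events are defined per station, the
sampling unit, not per physical camera.

Camera-days come from deployment spans — `(end − start)` in fractional days,
apportioned to calendar months pro-rata by overlap — rather than from photo
coverage, so a camera that detected nothing still contributes effort.
Seasons are warm (March–November) and winter (December–February).
RAI_j = 1000 · D_j / E_j per calendar month pooled across years; a month with
detections but no effort is a data-consistency error, never a silent division.

Rejected input rows (unparseable timestamps, negative deployment spans) are
returned in a rejects table with reasons, never dropped silently.

## Solar geometry and sun time

Event times are standardized against the sun because photoperiod at ~33° N
shifts sunrise by about two hours over the year.  Sunrise/sunset use the
low-precision closed-form geometry (solar declination + equation of time +
hour angle, threshold −0.833° for refraction and solar radius; −18° for
astronomical twilight), refined by three fixed-point iterations at the event
hour.  Against an independent Meeus-style ephemeris with numerical
root-finding the worst error over equinoxes/solstices is < 2 minutes —
negligible at camera-trap resolution.  All clock times are local standard
time (UTC+8 for the reference study area, configurable); no daylight saving.

Sun time maps sunrise to 06:00 and sunset to 18:00, linearly stretching
daylight between the anchors and night between 18:00 and next-day 06:00
(the night interval uses the same date's sunset and the next date's sunrise).
The map is a strictly increasing circular bijection per day; its inverse is
used by the synthetic generator.

Diel-period availability π̂ is accumulated per active station-date — each
date's crepuscular/diurnal/nocturnal windows intersected with the clipped
active interval — then normalized.  Computing it per station-date (rather
than from one representative schedule) is the literal reading of
"sum over all camera-trapping days", and the back-solved availability from
published selection-ratio tables (π̂_i = o_i / w_i, consistent across species
to ±0.003) confirms that convention: a typical warm season gives
approximately (0.125, 0.535, 0.34).

## Circular KDE and the overlap coefficient

Detection sun-times (angles, 1 h = π/12) are smoothed with a von Mises
kernel.  The kernel concentration is the plug-in rule

    κ_h = [ 3 n κ̂² I₂(2κ̂) / (4 √π I₁(κ̂)²) ]^{2/5} / adjust

with κ̂ the ML von Mises concentration (A₁(κ̂) = R̄, solved by bracketed
root-finding, capped at 500 for degenerate samples).  `adjust` is the
user-facing smoothing parameter, a divisor of the plug-in concentration with
default 1.0; κ̂ = 0 (uniform-like samples) falls back to a small positive
concentration (0.01) so the kernel stays proper.

The overlap coefficient Δ = ∫ min(f, g) is estimated two ways and both are
always reported: Δ̂1 (trapezoid integral of min(f̂, ĝ) on a 128-point grid;
4096 points in oracle checks) and Δ̂4 (the average of clipped density ratios
at the observed points).  The auto-selection threshold is 75 on the smaller
sample — Δ̂1 below, Δ̂4 above — following the simulation literature on these
estimators; either can be forced.  Δ̂4 of a sample with itself is exactly 1,
a useful identity test.

Confidence intervals use a smoothed bootstrap: each replicate redraws both
samples from the *fitted* densities (exact mixture sampling: a data point
plus von Mises(κ_h) noise), refits, and recomputes Δ̂; the percentile
interval is the default (basic and normal available).  Because both sides
are redrawn independently, replicates for identical inputs concentrate near
but below 1 — the point estimate sitting above the CI is logged, not fatal.

## Time-budget selection and randomization

Selection ratios w_i = (n_i/N)/π̂_i compare use to availability; χ² against
expected counts N·π̂_i (df = 2) screens for non-random use.  Per-period
significance and direction come from a multinomial randomization test:
n_reps (default 10,000) draws of multinomial(N, π̂), one-sided in the
direction of the observed deviation, with the add-one correction
p = (1 + #extreme)/(n_reps + 1) so p is never 0.  Two-period cases reduce to
the exact binomial tail, which the test matches within Monte-Carlo error;
its type-I error calibrates to 0.05 (±0.015 over 2,000 null surveys at
N = 200).  No multiplicity adjustment is applied across species.  Seasons
are analysed separately; species-seasons below a configurable minimum
detection count (default 10) are skipped.

## Two-species occupancy and the SIF

Latent site states follow (ψ_A, ψ_B, γ): P(both) = γψ_Aψ_B, etc.  γ is
optimized through a simplex-preserving transform — the joint probability is
a sigmoid-interpolated point of [max(0, ψ_A+ψ_B−1), min(ψ_A, ψ_B)] — so all
four state probabilities stay valid for any unconstrained parameter value.
Detection within an occasion is conditionally independent given the state;
a species uses p-parameters where it is alone and r-parameters where both
are present.  Covariates (lure age as a 4-level categorical with reference
bin 0–15 days; camera speed with reference *fast*) enter additively on the
logit scale with species-specific intercepts and covariate effects shared
across species.  When r is separate from p it gets its own full block
(intercepts and covariate effects).

Parameter counts under this convention: ψ(S)p(S) has K = 4;
ψ(S)p(S)r(S) K = 6; ψ(S)γ(·)p(S+Lr+Cam)r(S+Lr+Cam) K = 15.  Published
tables for this model family often use other counting conventions; this
package documents and reports its own rather than matching any particular
one, and comparisons across software should use −2LL and γ̂.

Occasions tile each deployment from its start in 15-day segments; a trailing
remnant ≥ 7.5 days is kept, shorter ones dropped.  Lure age is evaluated at
the occasion midpoint (start/midpoint/mean are all defensible; midpoint is
the symmetric choice).  The warm-season filter drops occasions whose
midpoint falls in December–February, for use when a species' winter
dormancy violates the closure assumption.

Fitting is L-BFGS-B with ≥3 random restarts from a seeded generator; SEs
come from the inverse of a central-difference observed-information matrix,
and γ's SE by the delta method through its transform.  A singular
information matrix (e.g. a covariate level never observed, such as lure age
> 45 days when deployments are shorter) is logged and yields NaN SEs without
failing the fit.  Models are ranked by AIC = −2LL + 2K; inference uses the
top set (ΔAIC < 2): *independence* when every top model fixes γ = 1,
*avoidance*/*aggregation* when all top models free γ and agree it is
below/above 1, *unclear* when the hypotheses mix.  Calibration: over 100
simulated 500-site × 6-occasion surveys at ψ_A = 0.5, ψ_B = 0.4, γ = 0.6,
p = r = 0.3, the mean γ̂ is within 0.05 of truth and Wald intervals cover at
~93–96%.

## Synthetic surveys

The generator emulates a Minshan-style survey: stations jittered around a
study-area centroid (default 32.9° N, 104.1° E), 4–6-week deployments inside
a survey window, scent lure applied at setup, fast/slow camera models, and
species defined by marginal occupancy ψ, a daily event rate, a von Mises
mixture diel archetype on sun time, and twelve monthly rate multipliers
(zero encodes winter dormancy).  Focal pairs draw their latent states
jointly from the four-state (ψ_A, ψ_B, γ) distribution; γ feasibility is
validated before simulation.  Events are an inhomogeneous Poisson process
converted from sun time to clock time through each station's actual solar
schedule, with occasional duplicate photos within 30 minutes to exercise the
independence filter.  The per-occasion detection probability implied by rate
λ over d days is 1 − exp(−λd).

What it does *not* emulate: spatial autocorrelation between stations, animal
movement or home ranges, detection distance/angle effects, camera failure
mid-deployment, or observer misidentification.  Passing tests on synthetic
surveys therefore validate the estimators under the model's own assumptions,
not robustness to field realities outside them.

The shipped `minshan-mini` fixture (60 stations, four species, pairs with
γ = 0.6 and 1.0, seed fixed) keeps the full-pipeline tests fast; estimator
calibration uses 500-site surveys, where the SIF is well identified.

## Numerical choices and limitations

* Density evaluations use exponentially scaled Bessel functions, stable to
  κ_h in the hundreds; densities are floored at 1e-12 inside ratio
  estimators and site likelihoods at 1e-300 before logs.
* The 128-point Δ̂1 grid agrees with 4096-point integration to ~3e-6 for
  plug-in-smoothed densities; 1e-3 is the guaranteed bound in tests.
* Bootstrap and randomization streams are seeded per species-pair /
  species-season from a master seed (CRC-based offsets), making every report
  bundle a pure function of (inputs, config, seed).
* Acceptance-style checks run at the sizes stated above (100 oracle
  instances, 100 calibration fits at 500 sites, 2,000 null surveys), chosen
  as the standard sizes for demonstrating calibration of this model family.
* Not implemented by design: lunar illumination or topographic horizon
  corrections, occupancy covariates (ψ is constant), multi-season dynamic
  occupancy, >2-species joint models, and distribution-equality tests
  (Watson-type) for diel samples.
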