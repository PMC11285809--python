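# Methods

This note documents the models, algorithms and design choices behind
`boarsleep`, in the spirit of a package methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Signal model and kinematics

Raw tag output is tri-axial acceleration in g at a nominal 20 Hz, axes
x = surge (anterior–posterior), y = sway (lateral), z = heave
(dorso-ventral); upright posture puts gravity mostly on z.  The static
(gravitational) component is estimated per axis by a **centred** running
mean over 2 s.  Two choices here are ours, because "running mean" alone
does not pin them down:

* *Centred, not trailing.*  A trailing filter delays posture estimates by
  half a window, which would systematically shift bout onsets scored at 1 s
  resolution; a centred filter has no lag.
* *Shrinking edge windows.*  At the trace edges the mean is taken over the
  available part of the window (partial means), so output length equals
  input length and per-second scoring has no NaN holes.

Window lengths are `round(window × fs)` forced odd so the window is
symmetric.  Pitch and roll are `arcsin(sx/‖s‖)` and `arcsin(sy/‖s‖)` in
degrees, with the argument clamped to [−1, 1]; normalising by ‖s‖ (rather
than assuming 1 g) guards against calibration drift and can be switched off
(`normalize_angles=False`).  Zero-magnitude static vectors produce NaN with
a warning, never silently.  VeDBA is the Euclidean norm of the dynamic
(raw − static) components; smoothed VeDBA is its 2 s running mean with the
same edge policy.  Traces with timestamp jitter beyond 10% of the nominal
interval are rejected; larger gaps are split into segments by the reader
(`io.read_trace`, gap threshold 2× the nominal interval).

## 2. Sleep classification

Per sample, lateral recumbency is `|roll| > 15°` (checked first) and
sternal recumbency is `pitch < 0°` and `|roll| < 15°`; everything else is
"other".  The printed lateral rule in the source literature
("roll < −15 and > +15") is logically empty as stated; we read it as the
disjunction `|roll| > 15°`.  All inequalities are strict: the boundary
values (pitch 0, |roll| 15, VeDBA 0.2) fall outside recumbency/stillness.

A sleep candidate is a maximal run of samples that are recumbent **and**
still (smoothed VeDBA < 0.2 g).  Posture switches between sternal and
lateral inside a run do not end it — bouts end on the movement threshold,
and postural adjustments during sleep are explicitly tolerated.  A single
supra-threshold sample ends the run; the 2 s smoothing already absorbs
transients, so no extra debounce is applied.  Candidates shorter than
5 min are discarded; survivors lose their first 5 min (wake-to-sleep
transition) and are dropped if nothing remains.  A candidate that passed
the 5-min filter is kept even if the trim leaves it under 5 min; the
stricter alternative is available (`drop_short_after_trim=True`).  Bouts
truncated by the recording edges are kept but flagged; daily filtering
drops partial days anyway.

`bout_oracle` is a deliberately naive one-sample state machine with the
same contract, used only as an independent cross-check in tests.

## 3. Daily metrics

Days are local civil midnight-to-midnight (IANA timezone, DST-aware; the
23/25-hour transition days are used as-is).  The anchor is our choice — DS
is sunrise/sunset-referenced, so calendar days in local time are least
surprising; a noon-to-noon option exists for nocturnal-sleep analyses.
A bout spanning midnight contributes its sleep seconds to each day it
overlaps but is *counted* once, in the day containing its post-trim start;
its longest-bout credit in that day is its within-day portion, which keeps
`longest_bout ≤ TST` per day.  The first and last calendar days of a
recording are dropped as incomplete.  DS is the percentage of a day's sleep
seconds falling between sunrise and sunset and is undefined (NaN, never 0)
on days without sleep.  The log of the longest bout is the natural log of
minutes, taken only when a bout exists.

Sunrise/sunset use the standard NOAA solar-position algorithm (Fourier
series for declination and the equation of time, zenith 90.833° for
refraction plus solar radius), implemented here directly; day lengths agree
with the independent `geosphere::daylength` oracle to within a few minutes
(frozen values in the test suite).  Polar day/night raises an error naming
the date; study latitudes (~50° N) are far from that regime.

## 4. Validation protocol

Predictions are reduced to 1 Hz by majority vote within each second (ties
count as recumbent); predicted recumbency runs shorter than 31 s — the
shortest recumbency bout in the validation footage the protocol emulates —
are removed; labelled seconds (covered ≥ 0.5 s by a label interval) are
then scored with recumbent as the positive class.  All four confusion
counts are reported so either positive-class convention can be recovered.
The real-data accuracy figures from video validation are not reproducible
without the video-matched traces; the synthetic benchmark in the test suite
requires ≥ 95% per-second accuracy at the default noise level instead.

## 5. Environmental covariates

Hourly weather is collapsed per site-date: means for temperature, humidity,
snow depth and cloud cover; total for precipitation.  Days with fewer than
75% of hourly records are flagged incomplete (the floor is configurable;
the choice is ours — the protocol we emulate does not address missing
hours).  Days with no records are absent, never silent zeros.  The
cloud-adjusted moon phase is `phase × (1 − cloud/100)`: cloud cover removes
its fractional share of moonlight.  Design matrices standardise continuous
covariates to mean 0, SD 1 (statistics stored for inverse transform);
quadratic terms are **raw squares of the standardised covariate** —
standardise first, then square — because raw polynomials are reproducible
without basis-construction ambiguity; an orthogonal-polynomial variant was
considered and left out.  Categorical covariates are one-hot coded against
a stated reference level (year reference 2019 in the intended analyses).

## 6. The double-hierarchical Gaussian model

With observation j of individual i:

    y_ij ~ Normal(X_ij'β_m + a_i,  exp(Z_ij'β_s + b_i)²)
    (a_i, b_i) ~ BVN(0; sd_a, sd_b, ρ)

The sigma part makes residual spread a modelled quantity: sd_b measures how
much individuals differ in day-to-day variability ("plasticity") and ρ asks
whether mean level and plasticity covary.  Priors: Normal(0, variance 100)
on fixed effects (we read "variance 100" literally, SD 10); half-t with 3
degrees of freedom on sd_a and sd_b, with the scale set to the response's
empirical SD (the protocol states the df but not the scale; tying the scale
to the response keeps the prior weakly informative on any response scale);
uniform(−1, 1) on ρ and on the optional AR(1) coefficient φ.  The AR(1)
applies to within-individual standardised residuals
(r_1 ~ N(0,1), r_t | r_{t−1} ~ N(φ r_{t−1}, 1−φ²)); it matches the
"per-individual order-1 autoregression" structure rather than any
package-specific syntax, and is off by default.

**Sampler.**  Adaptive Metropolis-within-Gibbs, chosen over HMC to avoid a
probabilistic-programming dependency and to keep seeding fully
deterministic; the model's dimension at desk scale does not need gradients.
Without AR(1):

* β_m and the a_i have Gaussian full conditionals and are updated by exact
  conjugate Gibbs draws;
* β_s is updated coordinate-wise by random-walk Metropolis, the b_i by a
  vectorised per-individual random walk (individuals are conditionally
  independent);
* (log sd_a, log sd_b, atanh ρ) move as one random-walk block with the
  appropriate Jacobians;
* one exact Gibbs *translation* move per iteration shifts each intercept
  against the mean of its random effects (likelihood-invariant, Gaussian
  conditional).  Without it the intercepts mix an order of magnitude
  slower — the usual fixed-intercept/random-mean confounding.

Proposal scales adapt by Robbins–Monro (targets 0.44 scalar, 0.3 block)
during burn-in only, so the post-burn-in kernel is fixed and valid.  With
AR(1) the conjugate shortcuts no longer hold and every block falls back to
random-walk Metropolis under the full AR(1) likelihood.  Default run:
4 chains × 6000 iterations, burn-in 1000, thin 5 — a desk-scale stand-in
for a 15000/1000/15 schedule, fully configurable.  Diagnostics are basic by
design: split-chain R̂ and a Geyer initial-positive-sequence effective
sample size (cross-checked against arviz in the tests).

Effects are summarised by the posterior median, 95% credible interval and
P_x — the percentage of draws on the opposite side of zero from the median
(median exactly zero: direction falls back to the mean, with a warning);
P_x < 5 flags a meaningful effect.  Random-effect SDs are positive by
construction, so P_x is not applied to them; a 95% CI away from zero is the
relevant evidence.  Stepwise model reduction (drop the weakest effect by
P_x, quadratics first, ties broken toward the later column) is a driver
loop the user runs by re-fitting with a reduced `FormulaSpec`, not a
packaged automatism.

`random_slope_fit` reuses the machinery for
`y_ij = β0 + β1 x_ij + u_i + v_i x_ij + ε`, with correlated (u_i, v_i),
conjugate Gibbs for β and the per-individual pairs, and random walks for
the scales; fixed effects there carry Normal(0, variance 10000) priors as
the emulated analyses specify for these models.

## 7. Synthetic data

The trace generator is the package's ground-truth instrument, not a boar
simulator.  Behaviour schedules are contiguous scripted entries; behaviour
orientations are synthetic stand-ins chosen to sit firmly inside/outside
the classification regions (non-recumbent pitch +30°, sternal −30°, lateral
roll +60°).  Transitions interpolate the gravity vector linearly over a 2 s
ramp — no physical sensor jumps orientation instantaneously — and the ramp
is placed so the classification-boundary crossing lands exactly half a
sample before the schedule boundary.  Because a centred running mean
reproduces linear segments exactly, the estimated posture then flips at
precisely the scheduled boundary sample, which is what makes noiseless
end-to-end recovery *exact* rather than merely close.  Entries into or out
of lateral recumbency route through the sternal orientation so every
entry/exit uses the same symmetric pitch ramp.  Activity is band-limited
2–5 Hz oscillation (two random tones per axis) under an envelope that
vanishes within 3 s of entry edges; the default amplitude 0.8 g puts
smoothed VeDBA around 0.5 g during activity, robustly above the 0.2 g
threshold.  The 2–5 Hz band is a stand-in — no spectral description of boar
locomotion informed it — and is only required to exceed the stillness
threshold robustly, not to mimic gait.  Sensor noise is additive Gaussian,
default 0.02 g per axis, which keeps the noiseless-limit tests meaningful
while stressing the classifier realistically; per-entry orientation jitter
(default 2°) perturbs posture angles.  Everything is deterministic given
the config seed.

`boar_schedule` scripts a mostly nocturnal animal: long daytime rests
(lognormal, median 30 min) with short active breaks, short nighttime rests
(median 9 min) with long activity, durations quantised to whole seconds so
entry boundaries stay on the 20 Hz sample grid.  It produces roughly
8–11 h of qualifying sleep per day over ~20–30 bouts, concentrated in
daylight — the regime the daily metrics and models are meant for.

What the generator does **not** emulate: real gait spectra, magnetometer or
GPS channels, tag slippage, temperature-dependent sensor drift, maternal or
social behaviour, or weather-coupled behaviour.  Passing tests therefore
show the *pipeline* is correct and robust to sensor noise; they do not
certify classification accuracy on field data, which requires video
validation.

The DHGLM simulator draws from exactly the model of the previous section
(optionally with AR(1)), returning both the observation table and the latent truth so
parameter-recovery experiments can score credible-interval coverage.

## 8. Numerical and scale choices

* Running means use cumulative sums (O(n), exact partial means at edges).
* Bout timestamps are nanosecond-resolution; a bout's `end` is the time of
  the sample *after* its last still sample, so durations are closed-open
  interval lengths and abut exactly.
* The parameter-recovery experiments run 40 individuals × 80 days with
  20 replicates at 2 chains × 2500 iterations (burn-in 800, thin 2), and
  the classifier benchmarks use 7-day schedules — sizes at which the whole
  test suite and the acceptance script complete in minutes on one CPU
  while leaving the recovery checks well powered.
* Seeds: all stochastic stages take explicit seeds; child seeds are spawned
  with `numpy.random.SeedSequence`, never reused across stages.

## 9. Known limitations

* Sleep is inferred behaviourally; wakeful rest in a sleep posture with
  near-zero movement is indistinguishable by construction, and REM/NREM
  staging is out of reach for accelerometry.
* The classifier thresholds (0°, 15°, 0.2 g, 5 min) are fixed field values,
  not fitted; tags mounted differently would need a re-derived axis
  convention.
* The DHGLM sampler is a random-walk method: posteriors with strong
  sigma-part correlations will mix slowly compared to HMC; R̂ and ESS are
  reported so users can judge.
* Moon phase is an input column; the package computes no lunar ephemerides.
* `environment` assumes one weather station per site; no spatial
  interpolation.
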