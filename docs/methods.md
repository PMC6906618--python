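# Methods

This note documents the models and procedures implemented in `gaitmon`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Signal model and conventions

Input is triaxial acceleration from a waist-worn sensor, nominally 100 Hz
with a ±6 g range, stored in units of g.  Axes: x = vertical, y = lateral,
z = longitudinal.  Timestamps are UTC internally; local calendar days come
from a per-subject timezone offset (`tz_offset_hours`, default 0), since
day-boundary handling must be explicit when sites span many timezones.
Recordings from multiple devices are merged onto one timeline per subject:
on overlap the earlier recording's samples win (deterministic and
order-independent after sorting by start time); gaps are annotated, never
imputed.

## Walking detection

* **Band.** 0.7–3 Hz covers the step-frequency range of slow to brisk
  walking.  The Butterworth band-pass (order 4) is applied
  forward-backward (`sosfiltfilt`) so it adds no group delay — window
  boundaries remain sample-aligned with the raw signal.
* **Windows.** 2.5 s windows with 50% overlap (hop 1.25 s).  2.5 s spans
  at least two strides even at low cadence, and 50% overlap is standard
  short-time practice that halves boundary loss.  The final partial window
  is discarded.
* **Dominant frequency.** Hann-tapered FFT per axis, zero-padded 4× for
  peak interpolation; the largest in-band peak counts as dominant only if
  it exceeds 3× the median in-band magnitude.  The ratio criterion is
  amplitude-scale-free: white noise has no dominant frequency under it
  (≥ 90% of noise windows rejected in tests), while even a weak periodic
  gait component passes.
* **Plausibility.** Windows are kept only if (checked in this order, the
  first failure recorded): the mean raw acceleration vector is within 45°
  of the vertical axis; the sd of the vector magnitude lies in
  [0.02 g, 2.0 g]; the vertical axis has a dominant frequency.  The
  activity measure is the standard deviation of the magnitude — one of
  several defensible choices (range and band energy being others); it was
  chosen for robustness to spikes, and the thresholds are config-exposed
  (`PlausibilityConfig`) for sensitivity analysis.  The 45° / 0.02 g
  defaults deliberately accept slow shuffling gait.

## Step parameterization and speed model

The analytic signal (Hilbert transform) of each band-passed walking
window yields per-axis envelope and unwrapped phase.  Summaries:
A = mean envelope, F = mean phase-derivative / 2π, both averaged over the
central 80% of the window because the analytic signal of a finite window
overshoots at its edges.  The mean (not max) envelope is used as the
amplitude summary for robustness to single-sample spikes.  If the
vertical instantaneous frequency drifts out of band on a noisy window,
the STFT dominant frequency (in band by construction) is used instead.

Speed is a per-window OLS projection on (A_x, A_y, A_z) and their three
pairwise products.  Interactions are read as pairwise only; a config flag
adds the three-way product, and another adds F_x as a predictor (off by
default — amplitude carries the speed signal in this model, and the
cadence term can be enabled for retraining experiments).  Predictions are
clamped to [0, 3] m/s, a physiological ceiling for this population that
prevents extrapolation artifacts.  The packaged default coefficients are
fitted to simulator output passed through the *real* pipeline
(`gaitmon.calibrate`), so they absorb band-pass attenuation and envelope
edge effects; they are synthetic-calibrated fixtures, not population
estimates, and `fit_speed_model` retrains on any labelled data in one
call (≥ 50 windows spanning ≥ 0.4 m/s required, rank-deficient designs
rejected).

Step accounting credits each window with F_x times the time it newly
covers (the advance since the previous walking window, capped at the
window length), so overlapping windows are not double-counted and a
bout's steps total ≈ cadence × duration.

## Bouts

Walking windows merge greedily left-to-right into a bout while (a) the
next window starts within `max_gap_s` of the previous one and (b) F_x
changes by at most 1.6-fold.  Defaults: `max_gap_s` = one hop (1.25 s),
reading contiguity literally; the 1.6-fold test compares adjacent windows
(a running-mean mode exists behind a flag, since the aggregate reading is
also defensible).  Bouts with fewer than 3 steps are discarded — it is
questionable whether such fragments constitute true walking — and their
steps are reported so accounting stays conserved.  Bout mean speed is
step-weighted, aligning with the per-step speed projection.  Length bins
are half-open [e_i, e_{i+1}) with edges 1, 5, 10, 20, 40, 80, 160, 320,
640 steps.

## Wear time and compliance

Worn/not-worn is decided per 60 s epoch: an epoch is still when every
axis's sd is below `still_sd_g` = 0.004 g, and a run of stillness of at
least 20 min becomes not-worn; unrecorded gaps are not-worn.  The floor
sits just above the at-rest noise of a 12-bit ±6 g sensor (LSB ≈ 0.003 g)
and well below any on-body signal; both parameters follow common
actigraphy practice and are config-exposed, because the 3 h threshold
below is only reproducible given an explicit detector.  Raising
`still_sd_g` can only shrink wear time (monotone by construction).

Daily summaries split wear seconds exactly at local midnight; a bout's
steps go whole to the day containing its start (this affects well under
one bout per day at realistic schedules).  Each visit defines a 20-day
epoch, days visit−10 … visit+10 with the visit day excluded.  When two
visit windows overlap, each day goes to the nearer visit (ties to the
earlier one) and a day that is some visit's own date is never counted —
no day is double-counted in cohort tables.  The two-component threshold
keeps a visit iff ≥ 3 days have ≥ 3 h wear; the exclusion report lists
every visit with its reason, so both the all-visits and
any-recording-in-window denominators can be formed.  Compliant days are
calendar days, not consecutive days.  The stabilization analyses bin the
hourly step rate by integer-floored wear hours and mean daily steps by
the number of compliant days.

## Clinic vs real-world comparison

Assessment intervals are cut from the raw stream at the recorded
timestamps with a ±2 s pad, sample-exact.  The estimated assessment speed
is the step-weighted mean of window predictions, reported as absent (not
an error) when fewer than 3 walking windows are found — e.g. a mistimed
recording of pure standing.  Agreement is OLS of estimate on reference
with RSE = √(SSR/(n−2)) and Pearson r, pooled across visits by default.

Validity pairs map 4mWT → [5, 20)-step bouts and 6MWT/400mWT →
[80, 640)-step bouts (half-open, matching the bin convention).  The
real-world side is the step-weighted mean over all in-range bouts in the
compliant epoch, excluding every calendar day containing any assessment
for that visit (conservative reading of "excluding the days of the
assessment"); a pair is omitted when no bouts land in range.

## The simulator: what it emulates and what it does not

The raw-signal generator synthesises walking as gravity plus a vertical
fundamental at the cadence, a 30% second harmonic, half-cadence lateral
and longitudinal components, and white sensor noise, with

* cadence = 1.2 + 0.7 · speed (Hz),
* A_x = 0.05 + 0.30 · speed, A_y = 0.03 + 0.12 · speed,
  A_z = 0.04 + 0.18 · speed (g), each with 5% multiplicative noise,
* sensor noise 0.02 g sd while worn, 0.0015 g at rest (below the 12-bit
  LSB, so the wear detector separates the two), postural sway at 0.3 Hz
  below the gait band for worn non-walking time.

These coefficients are fixtures chosen to resemble slow elderly gait;
they are not estimates of any population.  Signals are clipped at ±6 g
and optionally quantized to 12 bits.  Everything is bit-exact
reproducible from a seed.

Trial-scale raw signal (hundreds of subjects × weeks at 100 Hz) is not
generated; instead a derived-level generator produces bout/daily/visit
tables directly, encoding the relations the analytics must recover: an
hourly step rate around 410 steps/h that undercounts below 3 h of daily
wear, bout speed rising with bout length up to ~80 steps then
saturating, per-visit compliance labels drawn before the days (so the
threshold can be checked against truth exactly), and real-world
long-bout speed = 0.75 × clinic speed + noise (sd 0.05 m/s).

Because the gait waveform is harmonic, passing tests demonstrate that the
pipeline's operators (filtering, spectral dominance, Hilbert envelope,
linear projection, segmentation, accounting) recover known structure
correctly; they do not demonstrate accuracy on pathological gait
morphology, turning, stairs, or device artefacts, which only labelled
real recordings can establish.  The thin HDF5/delimited readers accept
common layout variants for externally deposited datasets.

## Numerical choices and degenerate inputs

Zero-phase filtering requires > ~45 samples; shorter inputs raise with
the minimum stated.  Recordings shorter than one window yield zero
windows (not an error).  All-zero windows are rejected by
parameterization (they should never survive classification).  Bout and
bin boundary comparisons use half-open intervals with a 1e-9 relative
tolerance on the 1.6-fold ratio so exact-equality sequences are stable.
Empty bout lists yield empty summaries; a day with zero wear has an
absent (None) step rate rather than a division by zero.  Merge drops
sub-sample overlaps silently and annotates gaps longer than 1.5 sample
periods.

## Problem sizes in the shipped checks

The test-suite and acceptance-script cohorts are sized for a laptop-class
run: 26 held-out subjects × 60 s walks for speed recovery (the
validation-study scale), 60-walk training sets (~2700 windows), 1000
random sequences for the segmentation oracle, 30–60 subjects × 3 visits
for the compliance and association analyses (~130–150 validity pairs).
At these sizes the recovered quantities sit well inside their tolerance
bands (e.g. speed-recovery RSE ≈ 0.03 m/s against a 0.10 m/s bound).

## Known limitations

* The speed model is linear in amplitudes; strongly nonlinear
  amplitude–speed relationships (e.g. very fast or highly asymmetric
  gait) would need the cadence term or a richer basis.
* Wear detection is purely kinematic; a perfectly still worn device
  (sleep) is classified not-worn after 20 min.
* Bout context is inferred from length only — no turning detection,
  indoor/outdoor inference, or GPS overlay.
* The default model ships synthetic-calibrated; absolute speed accuracy
  on real patients requires retraining on labelled recordings.
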