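# Methods

This note documents the models and procedures implemented in `ibisflight`,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical and design choices made where the
procedure was genuinely open.

## Signals and conventions

All per-flight series share one clock: seconds from session start, on the
ECG logger's time base (the ECG and accelerometer are co-housed in a
single unit, so no cross-device synchronization model is needed). ECG is
a single lead in mV (logger range ±6 mV) and acceleration three
body-frame axes in g (range ±8 g), both at 1600 Hz by default: surge
(antero-posterior), sway (lateral), heave (dorso-ventral, the
wingbeat-carrying axis). VeDBA is reported in milli-g.

## ECG → heart rate

**QRS detection.** The R-peak detector is an energy-based design in the
Pan–Tompkins tradition: zero-phase band-pass (2nd-order Butterworth,
default 10–45 Hz, which passes the R-spike energy and rejects baseline
wander and the ~5 Hz wingbeat artifact), squared derivative, moving-window
integration (40 ms), and peak-picking above an adaptive threshold.
Per 2 s window, the threshold sits a fraction (default 0.3) of the way
from the median integrated energy (the floor between beats) to its
99.5th percentile (the beat peaks); when a synchronized dynamic-heave
series is available the threshold is additionally raised in proportion
to the local mean |dynamic heave| (default gain 0.4 of the trace's
98th-percentile energy per g), so detection demands stronger evidence
while flapping shakes the electrodes. Candidates are height-filtered
only — a beat's energy can carry two slope lobes, and distance-pruning on
the raw maxima would let a tall secondary lobe suppress the next beat —
then refined to the extremum of the band-passed trace (making R-times
sample-accurate) with a refractory period of 60/HRmax s (default
75 ms at HRmax = 800 bpm) enforced on the refined times.

Degenerate inputs return an *empty* beat series with a diagnostic rather
than raising: a flat line is caught by a span check, and a noise-only
trace by an excess-kurtosis gate on the band-passed signal (band-passed
Gaussian noise has excess kurtosis ≈ 0; any train of QRS spikes measures
well above the default cut of 1 — empirically ≥ 2 even at 700 bpm, where
the duty cycle is highest).

**Density filter.** Each (time, HR) point's neighbor count is the number
of other points within ±2 s and ±20 bpm (both configurable); points are
ranked by count and the top ⌈keep_fraction · n⌉ retained (default 0.95),
with ties at the cut-off count all kept and temporal order preserved.
Physiological beats form a dense band in the time × rate plane; isolated
artifact detections drop out. The window sizes and keep rule are
explicit defaults of this implementation, not claimed to reproduce any
particular field workflow.

**Outlier window.** A deterministic physiological window (60–800 bpm
default) replaces visual outlier deletion, which is not reproducible.
Removal counts are carried in the series diagnostic.

**5 Hz resampling.** Instantaneous rate (60/RR of the most recent
interval) is placed on a uniform 5 Hz grid by zero-order hold. Grid
points more than `max_gap` (default 2 s) after the last retained beat are
emitted as missing (`NaN`, quality `"gap"`), never interpolated: holding
invents no values inside dropouts, whereas linear interpolation would.

## Acceleration → VeDBA

The static (gravity + posture) component of each axis is a centered
running mean over 1 s; edges use shrinking (truncated) windows so the
output keeps the input length without invented padding. Dynamic = raw −
static. VeDBA = √(d²ₓ + d²ᵧ + d²_z), computed per sample and reported
in mg. The 1 Hz series keeps the sample nearest each integer second —
literal sub-sampling (decimation), not block averaging, so every
retained value is a measured sample. The 1 Hz timestamps are the integer
seconds of the session clock.

## Flap/glide segmentation

Gliding is identified where |dynamic heave| < 300 mg for at least one
wingbeat (0.2 s); shorter sub-threshold runs (e.g. the ~25 ms
zero-crossing dwells inside a wingbeat cycle) are relabeled flapping in
a single pass, with no iterative run merging. The threshold applies to
the *dynamic* heave: the raw axis carries ~1 g of gravity in level
flight, which would make a raw-value rule unsatisfiable. Merging takes
the instantaneous state at each 1 Hz timestamp (not a majority vote over
the second) and the 5 Hz heart-rate value at that timestamp; rows with a
heart-rate gap are flagged, not dropped. Gliding proportion is the glide
share of 1 Hz rows; condition summaries report flights per bird,
recorded seconds, mean HR over non-missing rows, mean VeDBA, and the
pooled gliding proportion per housing × wind-angle condition.

## GPS → daily distance and migration onset

Daily path length connects all of a day's fixes with great-circle
(haversine) segments on a mean-radius sphere (R = 6371 km); at the
~100 km daily scale the spherical error against the ellipsoid is far
below the GPS sampling error. Fixes are bucketed by civil date in a
configurable timezone (default Europe/Rome, a single zone covering the
Tuscany–Alps corridor); segments never straddle midnight — each day is
scored on its own fixes only, and single-fix days score 0. A day with
path ≥ 50 km (inclusive) is a migration day. Migration starts on the
first of ≥ 2 consecutive days that each meet the 50 km rule *and* whose
net displacement bearing lies within ±90° of the great-circle bearing to
the breeding site, evaluated per day; the angle is a declared
operationalization of "toward the breeding site". The duration-reduction
figure is 100 · (A − B)/B for mean daily migration distances A and B:
over a fixed route, the ratio of daily distances maps directly to the
ratio of migration durations.

## Regression models

**Gliding proportion (OLS).** Treatment-coded design with intercept:
`gliding ~ shape × angle + bird`, reference levels cube, +2°, bird 310.
Closed-form least squares; σ̂² = RSS/(n − p); SEs from σ̂²(XᵀX)⁻¹; R² and
the overall F statistic reported. Rank deficiency raises.

**Daily distance (random-intercept LMM).** Distances are strongly
right-skewed, so the response is log₁₀ km (zero-distance days cannot be
transformed; they are excluded with an exclusion count — none arise under
the generator defaults). Fixed effects `attachment × activity` with
wing-loop and stopover as references; one random intercept per bird.
REML is profiled down to the variance ratio λ = σ²_b/σ²_e: with
V = I + λZZᵀ block-diagonal over birds, Woodbury gives
V⁻¹ᵢ = I − (λ/(1 + λnᵢ))J per group, so β̂(λ), the residual quadratic
form, log|V| and log|XᵀV⁻¹X| all reduce to group sums, and the scalar
criterion (n−p)·log σ̂² + log|V| + log|XᵀV⁻¹X| is minimized by bounded
Brent search on log λ with the λ = 0 boundary checked explicitly — so a
dataset with no between-group spread degenerates cleanly to OLS.
t-values are reported against the residual degrees of freedom (n − p).
This is a simplification of Satterthwaite-type degrees of freedom and is
anticonservative for between-bird contrasts when birds are few; interval
coverage for the attachment effect is nevertheless near-nominal at the
field-study scale (checked by simulation in the test suite). The
generalized additive mixed models sometimes fitted to the same 1 Hz
series (smooth random effects, AR1 residuals, scaled-t families) are
deliberately out of scope: this package emits the merged 1 Hz table such
fits consume, and the per-condition contrast summaries stand in for
their contrast plots.

## Synthetic data: what it emulates

* **Acceleration** — 1 g of gravity on the heave axis with a slow
  sinusoidal orientation drift (default ±10° at 0.1 Hz, so the
  running-mean static estimate is non-trivially exercised), a wingbeat
  oscillation during flapping bouts (default 5 Hz — one wingbeat per
  0.2 s — at 850 mg peak) and a sub-threshold residual during gliding
  (default 50 mg), plus white sensor noise (10 mg SD). Each bout gets a
  random initial phase: real wingbeats are not locked to the logger
  clock, and a phase-locked 5 Hz tone would alias against the 1 Hz
  decimation grid. Scripted plans also use a non-integer flap/glide
  cycle length for the same reason.
* **ECG** — Gaussian R-pulses (default full width 8 ms, amplitude 2 mV)
  placed where the integral of the piecewise-linear instantaneous rate
  crosses k − ½, plus baseline wander, white noise, and a motion
  artifact proportional to |dynamic heave|. Profiles whose shortest RR
  is under 3× the pulse width are rejected as unresolvable.
* **GPS** — migration days advance toward the breeding site along the
  great circle in equal steps summing to the day's target length;
  stopover days fly an out-and-back loop; per-fix isotropic jitter
  (σ = 15 m) is small against the 50 km scale. Fix counts per day follow
  the campaign's per-attachment averages (82 wing-loop, 52 leg-loop).

Campaign presets encode the study conditions: per-condition mean heart
rates (461/443/414/335 bpm for cube+2/drop+2/cube+6/drop+6), gliding
shares built from additive effects (0.280 reference; drop +0.085; +6°
+0.279; interaction +0.099; second bird −0.062), the 26-session
wind-tunnel layout, and the field study's 37 birds × 1060 bird-days with
log-scale effects (intercept 1.588; attachment 0.039; activity 0.449;
interaction 0.001; bird SD 0.004; residual SD 0.063). Within a session,
heart rate runs higher during flapping than gliding with the
duration-weighted mean pinned to the condition level; the roughly
one-third migration-day share in the field simulation is a realistic
spring-migration mix. Because the attachment effect acts on log-scale
(geometric) means, the simulated arithmetic migration-day means imply a
somewhat smaller duration reduction (~10%) than the 130 vs 113 km/day
reference means (15%); both are reported by `analysis/04`.

**Not emulated:** aerodynamics and drag, realistic PQRST morphology,
heart-rate variability structure, soaring vs flap-gliding styles,
altitude, weather-driven route variation, GPS dropouts, and device
failure. Passing tests therefore demonstrate that the pipeline recovers
the constructs it defines under controlled, physiologically plausible
signal structure — not that it is robust to every failure mode of field
recordings.

## Problem sizes and numerics

The simulated campaigns use 60 s flight sessions at 1600 Hz (26 sessions)
and full-scale field tables (1060 bird-days); the acceptance script runs
the same stages with 60 s ECG traces, 50 random flight plans, 20 random
itineraries, and 200 OLS replicates, completing in seconds. Numerical
tie-breaks: density-filter rank ties at the cut-off are all kept; the
1 Hz decimation takes the earlier sample on exact midpoints; the
boundary "minimum of 50 km" is inclusive; REML uses xatol 1e-10 on
log λ with λ capped at 1e4. Known limitations: the detector assumes
R-dominant beats of roughly constant polarity; the density filter is
O(n · window occupancy) and intended for single sessions, not multi-day
records; Satterthwaite degrees of freedom are not implemented; and the
migration-onset bearing window (±90°) is a convention, configurable per
call.
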