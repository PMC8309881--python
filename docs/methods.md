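# Methods

This document records the algorithms, parameter defaults and modelling
assumptions behind each stage of the pipeline, and the scope and limits of
the race simulator used for validation.

## 1. Track ingest and kinematics (`track_io`)

**Projection.** Fixes are projected onto a local plane with an
equirectangular approximation centred on the median fix: one metre of
northing per `R·π/180` degrees of latitude (WGS84 semi-major axis
`R = 6 378 137 m`), scaled by `cos(lat₀)` for easting. Over a course extent
of a few kilometres the scale error from latitude variation is below
0.05 %, which is negligible against GNSS noise; no external projection
library is needed.

**Speed.** Horizontal speed is the magnitude of the central finite
difference of planar position over time (`np.gradient`), then smoothed with
a 1.0 s centred moving average (edge-normalised; `smooth_window_s=0`
disables it). Central differences halve the phase lag of one-sided
differences; the 1 s window suppresses per-fix jitter without blurring the
~10 s speed transients that matter at race pace.

**Distance.** Cumulative distance is the running sum of planar step
lengths. Altitude is deliberately excluded here — course distances are
quoted horizontally; slope-corrected segment lengths are available via
`actual_distance` (hypotenuse of horizontal length and elevation
difference).

**IMU alignment.** The 100 Hz IMU stream is trimmed to the GNSS time span
and given per-sample speed and cumulative distance by linear interpolation
of the GNSS-derived series.

## 2. Course segmentation (`course`)

1. **Profile.** Altitude is interpolated onto a 5 m lap-distance grid for
   each lap separately and reduced by the point-wise median across laps
   (robust to single-lap GNSS excursions), then smoothed with a 30 m moving
   average.
2. **Breakpoints.** Candidate boundaries are sign changes of the smoothed
   gradient, with 20 m persistence hysteresis: a sign run shorter than 20 m
   is absorbed rather than opening a new segment.
3. **Refinement.** The 30 m smoothing biases zero crossings into adjacent
   weak-gradient sections, eroding short flats by 10–15 m. Each interior
   breakpoint is therefore re-fit as a free knot: within ±60 m it is moved
   to the position minimising the two-line least-squares error of the raw
   profile on both sides. This restored the flat share of the reference
   course to within 0.5 percentage points.
4. **Labelling.** A candidate segment is UPHILL or DOWNHILL when its net
   elevation difference reaches ±4 m (the minimum-elevation-difference
   rule); otherwise it is an undulating remainder.
5. **Merging.** Consecutive sub-threshold candidates merge into a single
   FLAT segment (even when their combined net difference would exceed the
   threshold — the rule is applied per monotone run), and adjacent
   same-label segments collapse.

Composition percentages are horizontal-length fractions of the lap.
Defaults: grid 5 m, smoothing 30 m, hysteresis 20 m, threshold 4 m.

## 3. Lap performance (`performance`)

- **Lap splits** at crossings of `k · lap_length` in cumulative distance,
  with the crossing time linearly interpolated and exact boundary points
  inserted, so lap distance axes start at 0 and end at the lap length.
- **Distance interpolation** of each lap's speed and elapsed time onto the
  common 5 m grid, then averaging across laps. This is the estimand all
  comparisons and distributions are computed on.
- **Group reference**: point-wise mean and sample standard deviation
  (`ddof=1`; a single-member group has SD 0).
- **Comparison**: absolute difference `ref − skier` (positive = slower),
  relative difference in percent of the reference speed, and accumulated
  time difference `skier.time − ref.mean_time`. Per-terrain aggregates
  assign each 5 m cell by its midpoint and weight by cell length; the
  per-terrain time losses tile the overall loss exactly.

## 4. Sub-technique classification (`subtechnique`)

- **Filtering**: 4th-order zero-phase Butterworth low-pass at 5 Hz
  (`sosfiltfilt`), applied once to the whole stream. Classical skiing
  cycle rates are 0.5–1.6 Hz; 5 Hz keeps several harmonics while removing
  sensor noise and vibration.
- **Windowing**: 200-sample (2.0 s) windows advanced by 10 samples (95 %
  overlap), giving `⌊(N − 200)/10⌋ + 1` windows for an N-sample stream.
  Each window carries the mean speed and the centre cumulative distance of
  its samples.
- **Features** (13): per channel (frontal-axis accelerometer and
  gyroscope): mean, SD, RMS, dominant frequency (zero-padded rFFT,
  nfft = 1024), spectral power share at the dominant frequency, and
  zero-crossing rate; plus the lag of the acc/gyr cross-correlation peak
  within ±1 s. These separate the techniques by cadence, amplitude and the
  characteristic phase relation between upper-body acceleration and
  rotation.
- **Classifier**: features are z-scored by the training statistics and
  classified by k = 5 nearest neighbours (Euclidean;
  `sklearn.neighbors.NearestNeighbors` is used for the search only). Votes
  tie-break by majority, then smallest mean neighbour distance, then fixed
  class order DP < DK < DIA < OTHER, making the result deterministic.
- **Distance labels**: window labels fold onto the 5 m lap grid by
  majority vote per cell (distances taken modulo the lap length);
  uncovered cells inherit the nearest covered cell. Manual corrections can
  be applied per window range; the corrected fraction is reported.
- **Training set**: generated deterministically by the simulator — 60
  windows per class rendered from each technique's cyclic signal template
  at a class-typical speed. It ships as code, not data, and can be
  replaced by any CSV with `f0..f12` + `label` columns.

## 5. Speed-binned distributions (`distribution`)

Each 5 m cell of the lap series contributes its length and dwell time to
the 0.25 m/s bin containing its midpoint speed (bins span 2–11 m/s).
Percentages are per bin and per class, weighted by distance or by time;
bins with less than 5 m total occupancy are flagged NaN rather than
zero-filled. Range summaries (low 2.75–4.75 m/s, high 7–10 m/s) are
occupancy-weighted over the bins in range. Group distributions are the
unweighted mean of member percentages, skipping members without occupancy
in a bin.

## 6. Race simulator (`simulate`)

The simulator exists to give every stage a ground truth.

- **Course**: ten legs with printed lengths and inclines tiling a 2465 m
  lap (37 % uphill, 15 % flat, 48 % downhill under the 4 m rule). For
  rendering, `CourseSpec.closed()` subtracts the constant incline trend
  (−0.41 %) so laps close in altitude; this changes no leg's label or the
  composition, but avoids a spurious altitude cliff at the lap wrap.
- **Speed dynamics**: `v(s) = clip(flat_speed − sensitivity · grade, 0.5,
  cap)` plus AR(1) noise (coefficient 0.9 per 5 m step), reflecting the
  strong distance correlation of real pacing. Defaults: flat speed
  6.8 m/s, sensitivity 0.38 (m/s per % grade), cap 10 m/s, noise SD
  0.15 m/s.
- **Technique ground truth**: a threshold rule on speed and grade — DIA
  above 4 % grade, DK above 1 %, OTHER when tucking (fast and/or steep
  descent), DP otherwise.
- **GNSS rendering**: the lap is laid out as a circle of matching
  circumference (closed, curvature everywhere, no self-intersection);
  fixes at 10 Hz with first-order Gauss-Markov noise (correlation time
  60 s; SD 0.5 m horizontal, 1.0 m vertical) — GNSS error is strongly
  autocorrelated, and white noise would inflate cumulative distance. A
  30 m overrun past the finish mimics not stopping the logger on the line.
- **IMU rendering**: per-class harmonic templates (cadence, acceleration
  and gyro amplitudes, phase relation) driven by a cumulative phase from
  the per-sample cadence, with 10 % per-cycle amplitude jitter and additive
  noise.
- **Seeding**: one integer seed spawns independent generators for speed,
  GNSS and IMU noise (`np.random.SeedSequence`), so simulations are exactly
  reproducible.

**Limits.** The simulator is a validation instrument, not a biomechanical
model: techniques switch instantly at rule boundaries, templates are
stationary harmonics rather than measured strides, the course has no
curvature-dependent speed loss, and GNSS error has no multipath or outage
structure. Conclusions about classifier performance on field data should
not be read off simulator accuracies.

## Validation summary

- Kinematics, segmentation, lap metrics and distributions are tested
  against closed-form and quadrature oracles; the KNN against a
  brute-force search with identical tie-breaks.
- End to end, on seeded default-noise 4-lap simulations, the pipeline
  recovers terrain composition within 2 percentage points, mean lap time
  within 1 s, ≥ 90 % per-distance sub-technique accuracy, and low/high
  speed-range distributions within 5 percentage points of ground truth
  (`tests/test_acceptance.py`).
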