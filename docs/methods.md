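# Methods

This note records the models implemented in `imugait`, the parameter
choices that matter, and the design decisions taken where the underlying
algorithm descriptions leave room.

## Signals and frames

All recordings are uniformly sampled 3-axis acceleration (m/s²) and 3-axis
rotational velocity (deg/s); the default sampling rate throughout is
60 Hz, the rate of the wearable system the pipeline targets, so one frame
is 16.7 ms. Event times are seconds internally and milliseconds in
reports. A recording is either in the raw *sensor* frame (axes x, y, z) or
in the *anatomical* frame with channels SI (superior-inferior), ML
(medial-lateral) and AP (anterior-posterior).

## Two-pose calibration

Standing still, the accelerometer reads the gravity reaction along the
body's SI axis; seated leaning back with legs extended, gravity tilts
within the sagittal plane. With **g**₁, **g**₂ the normalised mean
accelerations of the two poses:

    a = g1                (SI)
    b ∝ g2 × a            (ML)
    c = a × b             (AP)
    b := c × a            (re-orthogonalised ML)

The rows (a, b, c) form the direction-cosine matrix; anatomical components
of a sensor sample v are (v·a, v·b, v·c). Two deliberate choices:

- **Projection (row) form.** Writing the axis vectors as matrix *columns*
  would apply the transpose of this projection; only the row form maps
  sensor data *into* anatomical components, so that is what is
  implemented.
- **Handedness, not polarity.** Gravity fixes neither the left/right nor
  the forward/backward sign. The triad is forced right-handed
  (det = +1, flipping ML if necessary) and signal polarity is normalised
  downstream: every detector first flips the ML gyro channel if its
  dominant excursion is negative, making results independent of mounting
  side and seated-pose lean direction. The package asserts the
  consequence that matters: the calibrate→detect chain is invariant (to
  1 µs in event times) under any rigid rotation of the sensor frame.

Still windows default to 2 s; a pose is rejected as "not gravity
dominated" if the mean acceleration norm falls below g/2, and flagged as
"not still" above 10 deg/s RMS gyro magnitude.

## Event detectors

All five detectors share stride segmentation by the mid-swing peak of ML
rotational velocity: local maxima with prominence ≥ 50 % of the trial
maximum and spacing ≥ 0.6 s. The prominence fraction rejects swing-phase
secondary oscillations; 0.6 s corresponds to a cadence ceiling of about
100 strides/min per leg. Both are package choices where the source
algorithms are silent.

Per-peak search spans for the minima-, angle- and window-based detectors
are bounded by midpoints between adjacent peaks (guaranteeing disjoint
per-stride spans); at trial edges a half-median-stride fallback is used.
Extrema are reported at frame resolution and must be strict local extrema
(flat segments and window-edge hits are rejected, with a warning, rather
than mis-reported); zero crossings are linearly interpolated between the
bracketing samples, which is cheap and strictly reduces discretisation
error. An event whose feature is missing is omitted with a warning rather
than guessed.

Detector-specific decisions:

- **Sagittal angle (type 3).** θ(t) is the cumulative trapezoidal integral
  of ML rotational velocity. Drift is removed by a piecewise-linear
  correction forced to zero at anchors: on the foot, centres of stationary
  intervals (gyro magnitude < 15 deg/s for ≥ 0.1 s — the zero-velocity
  update); on the shank, which never stops during stance, midpoints
  between successive mid-swing peaks. Beyond the outermost anchors the
  adjacent segment's slope is extended. A constant gyro bias with anchors
  at both ends cancels exactly (the correction line is the drift).
  The search window around peak plantar-/dorsiflexion is ±150 ms — a
  parameter, not a claim about any published implementation.
- **Trusted swing (type 4).** The 20 % threshold is taken of each stride's
  *local* mid-swing peak value, not the trial maximum, so irregular
  strides keep a valid trusted-swing region. Only trusted swing (not
  trusted stance) is defined: a single-leg setup cannot gate stance.
- **HS window (type 5).** The 50 ms-before / 20 ms-after window around the
  post-peak ML velocity minimum is converted to frames by rounding
  outward (at 60 Hz: 3 frames back, 2 forward), so the boundary instants
  the millisecond window covers are never excluded. Which zero crossing
  yields TO is not fixed by the published description; the pre-peak upward
  crossing is used, consistent with the type-2 TO.

## Metrics and error summaries

Steps are (HS, TO, HS) triples between consecutive heel strikes with
exactly one interior TO; other HS pairs are skipped with a warning.
`stride` is stored as `stance + swing`, so the decomposition identity holds
exactly in floating point. Both streams are trimmed of their first and
last events (partial footfalls and gait initiation/termination at walkway
edges) before step construction. Device and reference steps are paired
greedily by nearest first-HS time with a 0.25 s cap — one-to-one coverage
cannot be assumed once detectors may drop events, and the cap prevents
cascading mispairs. Per factorial cell (metric × algorithm × location ×
task), pairs are pooled across trials/subjects and summarised as
RMSE = √mean(d²) and mean absolute bias = mean|d| ± SD(|d|) (sample SD),
in ms. Only rmse² ≥ (mean|d|)² (Jensen) is asserted as an invariant.

**Alignment.** The reference stream's clock is matched to the device by
the offset between first heel strikes, computed once per trial from the
dorsal-foot sensor (all sensors of a trial record synchronously) using the
velocity-minima detector. Residual sub-frame misalignment cancels in
duration metrics, which are within-stream differences. Caveat: if the
device stream misses the very first heel strike, first-HS alignment slips
by one stride; dataset manifests can therefore declare `"aligned": true`
when device and reference already share a clock (always the case for the
synthetic battery, whose reference *is* the ground truth).

## Synthetic generator

The generator is a feature-planting model, not musculoskeletal
simulation: the detectors consume only local extrema, zero crossings and
threshold excursions, so planting those features at known instants gives
exact, auditable ground truth. Per stride of period Tᵢ ~
N(1.05 s, 0.02 s²) with stance fraction 0.62 (typical self-paced healthy
walking):

- ML rotational velocity: slight negative stance baseline (−8 deg/s),
  sharp notches with vertices exactly at TO (depth 0.7 × 120 deg/s) and HS
  (120 deg/s) — HS reversals are deeper than pre-TO minima on real
  shanks, and the detectors' HS search windows rely on that ordering — a
  steep recovery crossing zero within ~8 ms of each event, a 60 deg/s
  swing plateau, and a Gaussian mid-swing bump peaking at 250 deg/s
  midway between TO and the next HS.
- AP acceleration: −5 m/s² spike at TO, +5 m/s² at HS. SI acceleration:
  −4 m/s² spike at HS (the channel is gravity-free; the detectors use
  only local minima, so a gravity baseline would be behaviour-neutral).
- White Gaussian per-channel noise (defaults 2 deg/s, 0.1 m/s²,
  representative MEMS figures at 60 Hz); stride periods are drawn before
  noise, so equal seeds give identical event timing across noise and
  artifact settings (paired comparisons).
- Optional heel artifact: in the 0.25 s before each TO the AP channel
  gains a positive ramp (amplitude 8 m/s²) with a superimposed
  oscillation, reproducing the heel-mounted sensor's tendency to
  oscillate positively before TO. This displaces the pre-swing AP minimum
  well before the event and degrades the trusted-swing detector's TO,
  while leaving the rotational-velocity detectors bit-identical.

A trial of n strides carries n HS and n TO truth events; the terminal
landing heel strike exists in the signal but not in the truth stream, so
detectors typically report the last stride's HS as an extra event (the
evaluation matches truth → detection and is unaffected).

What the generator does **not** emulate: gyro bias random walk (drift
robustness is exercised by a constant-bias closed-form test instead),
cross-axis coupling, soft-tissue resonance, double-support asymmetries,
turning, or realistic waveform morphology between the planted features.
Passing tests therefore demonstrate correctness of the *chain* —
calibration, feature extraction, event logic, metric algebra — under
controlled conditions, not clinical accuracy on any real population.

The benchmark battery is a desk-scale factorial: 5 location profiles
(differing mid-swing amplitudes; the heel profile carries the artifact) ×
2 tasks (stride jitter SD 0.02 s straight, 0.05 s obstacle) × 3 trials of
12 strides. Reproducing the published walkway-validation tables requires
the deposited study recordings, converted via
`scripts/convert_dataset.py`; the published numbers reflect visual
alignment and unstated peak-detection settings, so agreement within 15 %
relative (or 5 ms absolute) is the pass bar used for those cells.

## Degenerate inputs and numerics

- Calibration poses closer than 5° (or within 5° of antiparallel) leave
  the sagittal plane undefined and raise a degenerate-pose error naming
  the angle.
- Trials whose ML rotational velocity never exceeds 10 deg/s carry no
  gait content: detectors raise, peak finding returns empty.
- Uniform sampling is validated to 1 µs; CSV round-trips preserve numeric
  content to 1e-9 (values are written with nine decimals).
- Generator parameters whose planted features would overlap (stance
  < 0.35 s or swing < 0.2 s) are rejected rather than silently producing
  ambiguous ground truth.

## Known limitations

- First-HS alignment is not robust to a missed leading heel strike (see
  above); real-dataset manifests should either share clocks or contain a
  clean leading footfall.
- The five detectors are re-implementations of algorithm *families*;
  where the source descriptions are ambiguous the choices above apply, so
  numeric agreement with any specific original implementation is bounded
  by those ambiguities.
- No signal filtering is applied before detection, matching the study
  design this package serves; wavelet or IIR pre-filtering may change
  detector behaviour on real data.
- Spatial metrics (step length, velocity), left/right asymmetry and
  statistical testing between factorial cells are out of scope.
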