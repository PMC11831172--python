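# Methods

## The synthetic world

All validation rests on generators whose ground truth is known exactly.
They emulate the statistical structure the pipeline must handle, not the
photometric detail of real recordings.

### Eye images (`synthdata.gen_eye_image`)

A frame is a dark elliptical pupil inside a concentric iris ellipse (2.4×
the pupil axes) on a bright background, with three corruptions:

- a linear illumination gradient (up to ±0.8 gray/px), applied relative to
  the image center;
- corner shadow disks that darken pixels to a floor intensity, which may be
  darker than the pupil itself — the condition under which any fixed
  threshold picks up off-pupil pixels;
- seeded Gaussian pixel noise.

Intensities follow the dark-pupil ordering (pupil < iris < background); the
randomized family draws pupil semi-major axes of 9–17 % of the frame,
pupil gray 15–45, iris 80–140, background 170–230. The ground-truth mask is
exactly the pupil-ellipse interior. What the generator does **not** emulate:
corneal glints, eyelids/lashes, motion blur, perspective foreshortening of
the pupil. A green segmentation test therefore establishes robustness to
illumination structure, not to occlusion.

### Gaze trajectories (`synthdata.gen_gaze_trajectory`)

The horizontal channel alternates two regimes on a fine master grid (the
least common multiple of the eye and head rates, 720 Hz for 90/120):

- **Fixation:** head yaw drifts as a first-order autoregressive velocity
  process (stationary SD 5 °/s, correlation time 0.3 s); the eye
  counter-rotates at exactly `-vor_gain ×` head velocity (optionally plus
  white velocity noise). Composed gaze therefore moves at
  `(1 - vor_gain) ×` the head drift — zero under perfect VOR.
- **Shift:** raised-cosine (minimum-jerk-like) velocity bells, conjugate in
  eye and head. Gaze amplitudes are exponential (mean 8°) truncated to
  [8°, 80°]; the eye contribution is capped at 20° with the remainder
  assigned to the head; eye peak velocity follows the saturating law
  `v_peak = 400 · min(A, 10°)/10°` °/s, which fixes the eye bell duration
  at `2·A_eye/v_peak`; the head bell is 1.6× longer (slower, longer tail).
  Events arrive with exponential gaps plus a 150 ms refractory interval.
  Head drift is suppressed inside shift windows so programmed event
  amplitudes are exact ground truth.

The lower amplitude truncation at 8° is deliberate: with 90 Hz sampling and
any finite-difference velocity estimator, the 50 ms bells of smaller events
have sampled peak velocities below the ±200 °/s detection criterion, so
they are not gaze shifts under that definition and would make ground-truth
recovery ill-posed. Positions of shift bells use the closed-form
raised-cosine integral, so per-event eye + head amplitude equals gaze
amplitude to machine precision. Eye position is not mean-reverted between
shifts, so over long simulations eye-in-head position can wander beyond a
realistic oculomotor range; no kinematic statistic used here depends on
absolute eye position.

### Body tracks (`synthdata.gen_locomotion_track`)

Constant-speed bouts along random headings embedded in stillness, with
per-bout head heights. Ground-truth locomotion intervals are the bouts that
satisfy all three classification rules (speed > 5 cm/s, duration > 3 s,
head < 18 cm), so rule-violating bouts double as negative controls.

## Estimators and numerical choices

- **Velocity** is a centered moving average followed by central differences
  (one-sided at the ends). `compute_velocity` defaults to a 5-sample window;
  `segment_gaze` defaults to 3 samples (~33 ms at 90 Hz) because a 55 ms
  average attenuates the briefest (~50 ms) shift bells below the ±200 °/s
  threshold (gain ≈ 0.45). Both are config-exposed; the threshold is applied
  to the smoothed velocity.
- **Event boundaries** extend threshold crossings outward to the nearest
  gaze-velocity zero-crossing, so the eye-velocity reversal at shift end
  lands inside the event. Complement fragments shorter than the minimum
  fixation duration (50 ms) are absorbed into the preceding shift to keep
  the tiling invariant (between two shifts there is no fixation to merge
  into). Minimum shift duration (20 ms) is applied after extension.
- **Peak-velocity attenuation.** At 90 Hz, sampled + smoothed peak
  velocities of 50–100 ms bells read 10–25 % low. Amplitudes are unaffected
  (position differences over the full event). The main-sequence plateau/knee
  recovery check therefore simulates at 360 Hz, where the attenuation is a
  few percent; at 90 Hz the fitted plateau lands near 340–360 °/s for a
  400 °/s generator — an estimator property, reported as measured, not
  corrected.
- **Main-sequence fit**: continuous hinge `v = plateau · min(A, knee)/knee`,
  least squares with the plateau solved in closed form on a 0.25° knee grid.
- **VOR gain**: negated ordinary-least-squares slope of eye velocity on head
  velocity over pooled fixation samples, with each epoch shrunk by the
  velocity stencil so shift transients cannot leak in. With positional
  measurement noise on the head the estimate attenuates (errors-in-variables),
  which is why the end-to-end demo reports ~0.85 for a simulated 0.9; the
  recovery criterion uses velocity-level noise, where OLS is unbiased.
- **ApEn** is the Pincus form with self-matches and Chebyshev distance,
  tolerance `r·SD(x)`, defaults m = 2, r = 0.2 (field standard; config
  exposed). A constant series returns 0 by convention. The implementation
  is exactly equal (not approximately) to a brute-force double loop; rows
  are chunked so memory stays linear. Whether entropy is computed on
  position or velocity series is a declared option (`apen_on`), recorded in
  every report.
- **Locomotion filter**: 2nd-order Butterworth at 0.2 Hz applied forward and
  backward (zero phase). The zero-phase step response crosses 50 % at the
  step location, so for bouts at twice the speed threshold boundary error is
  small; the documented tolerance is 2 samples + 0.5 s of filter transient.
- **Calibration** is strictly per-axis affine (scale + offset) — the family
  the manual procedure exposes; no cross-axis or nonlinear terms. Segment
  distance uses the clamped point-to-segment projection; samples at exact
  scene on/off boundaries are excluded; error summaries report the median
  over registered samples (≤ 3.5°) and are available pooled and per session.
- **Segmentation network**: a pixel-wise MLP (15 features → 48 → 24 → 1,
  ReLU, sigmoid) trained with seeded mini-batch Adam (lr 3·10⁻³, batch 512)
  on binary cross-entropy. Per image, all pupil pixels are sampled plus 2×
  as many background pixels, half of them the darkest background pixels
  (hard negatives). Pixel-wise means any frame size is accepted at
  inference; training is bit-reproducible from (data, epochs, seed, config)
  and a saved/loaded model reproduces probability maps exactly. An
  encoder-decoder CNN would exploit shape context better, but no deep
  learning runtime is available in the supported environment; the feature
  design (band-pass blob channels, high-pass illumination cancellation, rim
  distance) carries that context instead, and meets the same IoU targets on
  the synthetic family.
- **Binarization** cutoff 0.5; baseline thresholding applies one
  morphological opening (disk radius 2 px); minimum component area 30 px².
  All defaults config-exposed.

## Behavioral-state analysis

Epochs tile the session. Shifts are assigned to the state containing their
midpoint. State contrasts (rate, amplitude, peak speed) use Wilcoxon
rank-sum tests, one per quantity, without multiple-testing correction —
matching per-contrast reporting conventions. Fixation-wise rms is pooled by
the state containing the fixation midpoint.

## Known limitations

- Only the horizontal channel (eye_h + head yaw) is segmented; vertical
  channels are carried through unmodified. Torsion and vergence are out of
  scope.
- The synthetic amplitude distribution and inter-shift interval law are
  declared, not fitted to recordings; recovery tests validate the
  estimators, not marmoset statistics.
- Peak-velocity readings at 90 Hz are attenuated as described above.
- The segmenter is trained and validated on the synthetic family; transfer
  to real eye video would require retraining on annotated frames (the
  training loop accepts any image/mask set).
- The world-camera pixel-to-degree conversion (field of view) enters only
  through configuration; no lens-distortion model is applied.
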