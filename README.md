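# headgaze

Analysis software for head-mounted eye tracking in freely moving small
primates: pupil segmentation from eye-camera frames, pupil-to-world gaze
calibration with geometric error estimation, and a gaze-kinematics pipeline
(gaze-shift/fixation segmentation, main sequence, VOR gain, rms stability,
approximate entropy, locomotion classification). Every stage is testable
against synthetic data with known ground truth, so the whole pipeline runs
and validates without any recorded data.

## Who it is for

Labs quantifying natural visual behavior in freely moving animals with a
head-mounted eye camera (~90 Hz) and a motion-capture head/body stream
(~120 Hz). In that setting the eye camera measures *eye-in-head* angle only;
the direction of the visual axis in the world — gaze — is the sum of
eye-in-head angle and head orientation:

```
gaze_h(t) = eye_h(t) + head_yaw(t)
```

Gaze alternates between **gaze shifts** (rapid conjugate eye+head movements,
the freely-moving analog of saccades) and **gaze fixations**, during which
the vestibulo-ocular reflex (VOR) counter-rotates the eye against head drift.

## The core methods

- **Pupil detection.** A fixed intensity threshold finds a dark pupil only
  under even illumination; shadows and gradients defeat it. The trainable
  segmenter classifies each pixel from a multi-scale feature vector
  (Gaussian pyramid, difference-of-Gaussian band-pass channels, high-pass
  intensity, local contrast, image-plane position) with a small seeded
  network; the mask is reduced to an ellipse-fit center
  (largest connected component, least-squares conic on the boundary).
- **Calibration.** Per-axis affine map `deg = gain · px + offset`, fitted by
  least squares to paired pupil/target points. Accuracy against known scene
  geometry is the nearest-feature error: distance to the closest active
  point or line segment, with samples beyond a 3.5° bound not registered as
  looking at the feature; the summary is the median over registered samples.
- **Segmentation.** Gaze shifts are runs where |gaze velocity| exceeds
  ±200 °/s, extended outward to the surrounding velocity zero-crossings;
  everything else is fixation. Per-event amplitude, peak velocity, latency
  to peak and duration are reported for eye, head and gaze.
- **Kinematics.** Main sequence with a saturating (hinge) fit of eye peak
  velocity vs. gaze amplitude; VOR gain as the negated slope of eye-on-head
  velocity regression during fixations; rms stabilization within fixations;
  approximate entropy (Pincus ApEn, m = 2, r = 0.2·SD); locomotion
  classification by three rules (body speed > 5 cm/s after a 0.2 Hz
  zero-phase low-pass, duration > 3 s, head height < 18 cm).

## Worked example

```sh
headgaze run --seed 1 --out demo/
```

simulates a 60 s freely-moving session (90 Hz eye, 120 Hz head), renders
calibration frames, detects the pupil, fits the calibration, aligns the
streams, segments gaze and writes `demo/report.json`. With seed 1 the
report contains (values printed by the run):

```
vor_gain:          {"gain": 0.846, "se": 0.005, "n": 4732}   # simulated gain 0.9
gaze_rms:          0.142 deg      # gaze ~8x more stable than head
head_rms:          1.191 deg
approximate_entropy: eye_h 0.020, gaze_h 0.019
median gaze error: 0.268 deg over 178 registered samples
```

The VOR estimate sits slightly below the simulated 0.9 because it is taken
from *detected* fixations of a noisy recording rather than ground-truth
epochs — the honest end-to-end number. The calibration error median is well
under 1°, and composed gaze is several times more stable than the head, the
signature of compensatory eye movements.

Library use mirrors the CLI:

```python
from headgaze import synthdata, gaze, kinematics

spec = synthdata.TrajectorySpec(duration=60, vor_gain=0.9, seed=1)
eye, head, truth = synthdata.gen_gaze_trajectory(spec)
series = gaze.align_streams(eye, head)
events = gaze.segment_gaze(series, v_threshold=200.0)
table, binned, fit = kinematics.main_sequence(events)
res = kinematics.vor_gain(series, truth.fixation_intervals)
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire pipeline from scratch under the given seed — synthetic
recording, segmenter training path, calibration, error estimation,
segmentation and the kinematics report — leaving all intermediate outputs
under `results/pipeline/` and the results JSON at the given path.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
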