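"""Synthetic inputs with known ground truth for every pipeline stage.

Three families of generators:

* eye-camera images — a dark elliptical pupil inside a mid-gray iris on a
  bright background, optionally corrupted by an illumination gradient and
  dark corner shadows (the conditions under which plain intensity
  thresholding picks up off-pupil pixels);
* gaze/head trajectories — saw-tooth eye traces in which rapid conjugate
  eye+head gaze shifts alternate with gaze fixations during which the eye
  counter-rotates against head drift (vestibulo-ocular reflex with a known
  gain), obeying a main-sequence law with an eye-velocity plateau and an
  eye-amplitude ceiling;
* body/head tracks — locomotion bouts of known speed, duration and head
  height embedded in stationary epochs.

Every generator is a pure function of its spec (including the seed): the
same spec reproduces the same output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from headgaze.calibrate import ScenePrimitive

__all__ = [
    "EyeImageSpec",
    "TrajectorySpec",
    "GroundTruth",
    "gen_eye_image",
    "sample_eye_image_spec",
    "gen_eye_image_batch",
    "gen_gaze_trajectory",
    "gen_locomotion_track",
    "gen_scene_shapes",
    "schedule_scene",
]


# ---------------------------------------------------------------------------
# Eye images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyeImageSpec:
    """Parameters of one synthetic eye-camera frame.

    The dark-pupil convention is enforced:
    ``pupil_intensity < iris_intensity < background_intensity``.
    ``illumination_gradient`` is (gray per pixel along rows, along columns),
    applied relative to the image center.  ``shadow_blobs`` is a sequence of
    ``((row, col), radius, intensity)`` disks that darken the image to at
    most ``intensity`` (emulating corner shadows from the camera housing).
    """

    image_size: tuple[int, int] = (96, 96)
    pupil_center: tuple[float, float] = (48.0, 48.0)
    pupil_axes: tuple[float, float] = (14.0, 10.0)  # (semi-major, semi-minor), px
    pupil_angle: float = 0.0  # radians, major axis from the column axis
    pupil_intensity: float = 30.0
    iris_intensity: float = 110.0
    background_intensity: float = 200.0
    illumination_gradient: tuple[float, float] = (0.0, 0.0)
    shadow_blobs: tuple = ()
    noise_sd: float = 0.0
    seed: int = 0

    # iris drawn as a concentric ellipse this many times the pupil axes
    iris_scale: float = 2.4


def _validate_eye_spec(spec: EyeImageSpec) -> None:
    h, w = spec.image_size
    a, b = spec.pupil_axes
    if not (a >= b > 0):
        raise ValueError(f"pupil_axes must satisfy semi-major >= semi-minor > 0, got {spec.pupil_axes}")
    if not (spec.pupil_intensity < spec.iris_intensity < spec.background_intensity):
        raise ValueError(
            "dark-pupil convention violated: require pupil_intensity < iris_intensity "
            f"< background_intensity, got ({spec.pupil_intensity}, {spec.iris_intensity}, "
            f"{spec.background_intensity})"
        )
    c, s = math.cos(spec.pupil_angle), math.sin(spec.pupil_angle)
    half_col = math.hypot(a * c, b * s)
    half_row = math.hypot(a * s, b * c)
    r0, c0 = spec.pupil_center
    if r0 - half_row < 0 or r0 + half_row > h - 1 or c0 - half_col < 0 or c0 + half_col > w - 1:
        raise ValueError(
            f"pupil_center/pupil_axes place the pupil ellipse outside the {h}x{w} image bounds"
        )


def _ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dr = rr - center[0]
    dc = cc - center[1]
    c, s = math.cos(angle), math.sin(angle)
    u = dc * c + dr * s  # along major axis
    v = -dc * s + dr * c
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def gen_eye_image(spec: EyeImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one eye frame and its ground-truth pupil mask.

    Returns ``(image, mask)``: a float image clipped to [0, 255] and a
    boolean mask that is exactly the set of pixels inside the pupil ellipse.
    """
    _validate_eye_spec(spec)
    h, w = spec.image_size
    mask = _ellipse_mask((h, w), spec.pupil_center, spec.pupil_axes, spec.pupil_angle)
    iris = _ellipse_mask(
        (h, w),
        spec.pupil_center,
        (spec.pupil_axes[0] * spec.iris_scale, spec.pupil_axes[1] * spec.iris_scale),
        spec.pupil_angle,
    )
    img = np.full((h, w), spec.background_intensity, dtype=float)
    img[iris] = spec.iris_intensity
    img[mask] = spec.pupil_intensity

    gr, gc = spec.illumination_gradient
    if gr or gc:
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        img += gr * (rr - (h - 1) / 2.0) + gc * (cc - (w - 1) / 2.0)

    for (br, bc), radius, intensity in spec.shadow_blobs:
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        blob = (rr - br) ** 2 + (cc - bc) ** 2 <= radius**2
        img[blob] = np.minimum(img[blob], intensity)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    return np.clip(img, 0.0, 255.0), mask


def sample_eye_image_spec(
    rng: np.random.Generator,
    image_size: tuple[int, int] = (96, 96),
    shadow_prob: float = 0.6,
    gradient_prob: float = 0.7,
    noise_sd_range: tuple[float, float] = (0.0, 0.0),
) -> EyeImageSpec:
    """Draw one spec from the randomized synthetic eye-image family.

    Pupil geometry, intensities, gradients and corner shadows are sampled
    over ranges wide enough that fixed-threshold detection fails on a
    sizeable fraction of the family while the true mask is always known.
    """
    h, w = image_size
    major = rng.uniform(0.09, 0.17) * min(h, w)
    minor = major * rng.uniform(0.6, 1.0)
    angle = rng.uniform(0.0, math.pi)
    margin = major + 2.0
    center = (rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin))
    pupil = rng.uniform(15.0, 45.0)
    iris = rng.uniform(max(pupil + 30.0, 80.0), 140.0)
    bg = rng.uniform(170.0, 230.0)
    gradient = (0.0, 0.0)
    if rng.random() < gradient_prob:
        mag = rng.uniform(0.2, 0.8)
        theta = rng.uniform(0.0, 2 * math.pi)
        gradient = (mag * math.sin(theta), mag * math.cos(theta))
    blobs = []
    if rng.random() < shadow_prob:
        for _ in range(rng.integers(1, 3)):
            corner = rng.integers(0, 4)
            br = rng.uniform(0, 0.2 * h) if corner < 2 else rng.uniform(0.8 * h, h)
            bc = rng.uniform(0, 0.2 * w) if corner % 2 == 0 else rng.uniform(0.8 * w, w)
            blobs.append(((br, bc), rng.uniform(0.1, 0.25) * min(h, w), rng.uniform(5.0, 40.0)))
    return EyeImageSpec(
        image_size=image_size,
        pupil_center=center,
        pupil_axes=(major, minor),
        pupil_angle=angle,
        pupil_intensity=pupil,
        iris_intensity=iris,
        background_intensity=bg,
        illumination_gradient=gradient,
        shadow_blobs=tuple(blobs),
        noise_sd=rng.uniform(*noise_sd_range),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def gen_eye_image_batch(
    n: int,
    seed: int = 0,
    image_size: tuple[int, int] = (96, 96),
    **family_kwargs,
) -> tuple[np.ndarray, np.ndarray, list[EyeImageSpec]]:
    """Generate ``n`` frames from the randomized family (images, masks, specs)."""
    rng = np.random.default_rng(seed)
    specs = [sample_eye_image_spec(rng, image_size=image_size, **family_kwargs) for _ in range(n)]
    pairs = [gen_eye_image(s) for s in specs]
    images = np.stack([p[0] for p in pairs])
    masks = np.stack([p[1] for p in pairs])
    return images, masks, specs


# ---------------------------------------------------------------------------
# Gaze / head trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of a synthetic freely-moving gaze recording.

    Gaze shifts arrive as a Poisson-like process (exponential gaps plus a
    refractory interval) with gaze amplitudes drawn from an exponential
    distribution (mean ``amplitude_mean``) truncated to
    [``amplitude_min``, ``amplitude_max``].  The eye contribution to each
    shift is capped at ``eye_saturation_amplitude``; the remainder is
    assigned to the head.  Eye peak velocity follows a saturating main
    sequence: linear in gaze amplitude up to ``eye_vpeak_knee`` degrees and
    flat at ``eye_vpeak_plateau`` deg/s beyond.  During fixations the head
    drifts as a first-order autoregressive velocity process and the eye
    counter-rotates at ``-vor_gain`` times head velocity.
    """

    duration: float = 60.0
    eye_rate: float = 90.0
    head_rate: float = 120.0
    shift_rate: float = 1.0  # events per second
    amplitude_mean: float = 8.0
    amplitude_min: float = 8.0
    amplitude_max: float = 80.0
    vor_gain: float = 0.9
    head_drift_sd: float = 5.0  # deg/s, stationary SD of head drift velocity
    drift_tau: float = 0.3  # s, AR(1) correlation time of head drift
    measurement_noise_sd: float = 0.0  # deg, added to sampled positions
    eye_velocity_noise_sd: float = 0.0  # deg/s, white noise on compensatory eye velocity
    eye_saturation_amplitude: float = 20.0  # deg, eye contribution ceiling
    eye_vpeak_plateau: float = 400.0  # deg/s
    eye_vpeak_knee: float = 10.0  # deg, gaze amplitude at which eye velocity saturates
    head_dur_factor: float = 1.6  # head profile duration / eye profile duration
    refractory: float = 0.15  # s, minimum gap between successive shifts
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for name in ("eye_rate", "head_rate", "shift_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.vor_gain <= 1.2:
            raise ValueError(f"vor_gain must lie in [0, 1.2], got {self.vor_gain}")
        if self.shift_rate * self.refractory >= 1.0:
            raise ValueError(
                f"shift_rate {self.shift_rate}/s conflicts with the {self.refractory*1e3:.0f} ms "
                "refractory gap: events would overlap"
            )


@dataclass
class GroundTruth:
    """Event-level labels embedded in a generated trajectory."""

    shift_intervals: list[tuple[float, float]] = field(default_factory=list)
    amp_eye: np.ndarray = field(default_factory=lambda: np.empty(0))
    amp_head: np.ndarray = field(default_factory=lambda: np.empty(0))
    amp_gaze: np.ndarray = field(default_factory=lambda: np.empty(0))
    eye_peak_velocity: np.ndarray = field(default_factory=lambda: np.empty(0))
    head_peak_velocity: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_vor_gain: float = float("nan")
    duration: float = float("nan")
    locomotion_intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def fixation_intervals(self) -> list[tuple[float, float]]:
        """Complement of the shift intervals within [0, duration]."""
        out = []
        t = 0.0
        for t0, t1 in self.shift_intervals:
            if t0 > t:
                out.append((t, t0))
            t = t1
        if t < self.duration:
            out.append((t, self.duration))
        return out


def _raised_cosine_pos(t: np.ndarray, t0: float, dur: float, amp: float) -> np.ndarray:
    """Closed-form position of a raised-cosine velocity bell (0 before, amp after)."""
    s = np.clip((t - t0) / dur, 0.0, 1.0)
    return amp * (s - np.sin(2 * np.pi * s) / (2 * np.pi))


def gen_gaze_trajectory(
    spec: TrajectorySpec,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate eye-in-head and head-orientation streams with ground truth.

    Returns ``(eye_series, head_series, truth)`` where ``eye_series`` has
    columns ``t_s, eye_h_deg, eye_v_deg`` on the eye-camera grid and
    ``head_series`` has ``t_s, head_yaw_deg, head_pitch_deg`` on the
    (denser) head-tracker grid; both grids share the clock origin t = 0.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    eye_rate, head_rate = spec.eye_rate, spec.head_rate
    if abs(eye_rate - round(eye_rate)) > 1e-9 or abs(head_rate - round(head_rate)) > 1e-9:
        master_rate = 8.0 * max(eye_rate, head_rate)
    else:
        master_rate = float(math.lcm(int(round(eye_rate)), int(round(head_rate))))
    dt = 1.0 / master_rate
    n = int(round(spec.duration * master_rate)) + 1
    t = np.arange(n) * dt

    # --- draw gaze-shift events ----------------------------------------
    events = []
    t_cursor = 0.25  # settle-in margin before the first shift
    while True:
        gap = rng.exponential(1.0 / spec.shift_rate)
        t0 = t_cursor + gap
        # truncated exponential amplitude via inverse CDF (handles the
        # degenerate amplitude_min == amplitude_max case too)
        f_lo = 1.0 - math.exp(-spec.amplitude_min / spec.amplitude_mean)
        f_hi = 1.0 - math.exp(-spec.amplitude_max / spec.amplitude_mean)
        u = f_lo + rng.random() * (f_hi - f_lo)
        amp = -spec.amplitude_mean * math.log1p(-u) if u < 1.0 else spec.amplitude_max
        sign = 1.0 if rng.random() < 0.5 else -1.0
        amp_eye = min(amp, spec.eye_saturation_amplitude)
        amp_head = amp - amp_eye
        vpeak_eye = spec.eye_vpeak_plateau * min(amp, spec.eye_vpeak_knee) / spec.eye_vpeak_knee
        dur_eye = 2.0 * amp_eye / vpeak_eye
        if amp_head > 0:
            dur_head = dur_eye * spec.head_dur_factor
            vpeak_head = 2.0 * amp_head / dur_head
        else:
            dur_head, vpeak_head = 0.0, 0.0
        dur = max(dur_eye, dur_head)
        if t0 + dur > spec.duration - 0.1:
            break
        events.append((t0, dur, sign, amp, amp_eye, amp_head, dur_eye, dur_head, vpeak_eye, vpeak_head))
        t_cursor = t0 + dur + spec.refractory

    # --- head drift (AR(1) velocity), suppressed inside shifts ---------
    rho = math.exp(-dt / spec.drift_tau)
    innov = rng.normal(0.0, spec.head_drift_sd * math.sqrt(1.0 - rho**2), size=n)
    innov[0] = rng.normal(0.0, spec.head_drift_sd)  # stationary start
    drift_v = signal.lfilter([1.0], [1.0, -rho], innov)
    in_shift = np.zeros(n, dtype=bool)
    for t0, dur, *_ in events:
        i0, i1 = int(math.ceil(t0 / dt)), int(math.floor((t0 + dur) / dt))
        in_shift[i0 : i1 + 1] = True
    drift_v[in_shift] = 0.0
    drift_pos = np.concatenate([[0.0], np.cumsum(0.5 * (drift_v[1:] + drift_v[:-1]) * dt)])

    # --- compose positions ---------------------------------------------
    head_yaw = drift_pos.copy()
    eye_h = -spec.vor_gain * drift_pos
    if spec.eye_velocity_noise_sd > 0:
        # white velocity noise on the compensatory (fixation) eye channel
        vnoise = rng.normal(0.0, spec.eye_velocity_noise_sd, size=n)
        vnoise[in_shift] = 0.0
        eye_h = eye_h + np.concatenate([[0.0], np.cumsum(0.5 * (vnoise[1:] + vnoise[:-1]) * dt)])
    for t0, dur, sign, amp, amp_eye, amp_head, dur_eye, dur_head, _, _ in events:
        eye_h += _raised_cosine_pos(t, t0, dur_eye, sign * amp_eye)
        if amp_head > 0:
            head_yaw += _raised_cosine_pos(t, t0, dur_head, sign * amp_head)

    # small independent vertical channels (carried through, never segmented)
    eye_v = _ar1_series(rng, n, dt, tau=0.5, sd=0.3)
    head_pitch = _ar1_series(rng, n, dt, tau=0.5, sd=1.0)

    # --- sample onto the two instrument grids ---------------------------
    eye_step = int(round(master_rate / eye_rate))
    head_step = int(round(master_rate / head_rate))
    ei = np.arange(0, n, eye_step)
    hi = np.arange(0, n, head_step)
    noise = spec.measurement_noise_sd
    eye_df = pd.DataFrame(
        {
            "t_s": t[ei],
            "eye_h_deg": eye_h[ei] + (rng.normal(0, noise, ei.size) if noise > 0 else 0.0),
            "eye_v_deg": eye_v[ei] + (rng.normal(0, noise, ei.size) if noise > 0 else 0.0),
        }
    )
    head_df = pd.DataFrame(
        {
            "t_s": t[hi],
            "head_yaw_deg": head_yaw[hi] + (rng.normal(0, noise, hi.size) if noise > 0 else 0.0),
            "head_pitch_deg": head_pitch[hi] + (rng.normal(0, noise, hi.size) if noise > 0 else 0.0),
        }
    )

    truth = GroundTruth(
        shift_intervals=[(e[0], e[0] + e[1]) for e in events],
        amp_eye=np.array([e[2] * e[4] for e in events]),
        amp_head=np.array([e[2] * e[5] for e in events]),
        amp_gaze=np.array([e[2] * e[3] for e in events]),
        eye_peak_velocity=np.array([e[8] for e in events]),
        head_peak_velocity=np.array([e[9] for e in events]),
        true_vor_gain=spec.vor_gain,
        duration=spec.duration,
    )
    return eye_df, head_df, truth


def _ar1_series(rng, n, dt, tau, sd) -> np.ndarray:
    rho = math.exp(-dt / tau)
    innov = rng.normal(0.0, sd * math.sqrt(1 - rho**2), size=n)
    innov[0] = rng.normal(0.0, sd)
    return signal.lfilter([1.0], [1.0, -rho], innov)


# ---------------------------------------------------------------------------
# Body / head tracks with locomotion bouts
# ---------------------------------------------------------------------------

def gen_locomotion_track(
    duration: float,
    rate: float = 120.0,
    bouts: Sequence[tuple[float, float, float]] = (),
    head_height_cm: float | Sequence[float] = 10.0,
    baseline_head_height_cm: float = 22.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[float, float]]]:
    """Simulate a body-position track with labeled locomotion bouts.

    ``bouts`` is a sequence of ``(t_start, t_end, speed_cm_s)``; during each
    bout the body moves at the given constant speed along a random heading,
    otherwise it is still (plus optional seeded jitter).  ``head_height_cm``
    applies inside bouts (scalar or one value per bout);
    ``baseline_head_height_cm`` applies elsewhere.

    Returns a track DataFrame (``t_s, x_cm, y_cm, head_z_cm``) and the list
    of ground-truth locomotion intervals, i.e. the bouts that satisfy the
    classification rules: speed above 5 cm/s, duration above 3 s, and head
    height below 18 cm.
    """
    bouts = sorted(bouts)
    for (a0, a1, sp) in bouts:
        if a1 <= a0:
            raise ValueError(f"bout ({a0}, {a1}) has nonpositive duration")
        if sp < 0:
            raise ValueError("bout speeds must be >= 0")
    for (a0, a1, _), (b0, b1, _) in zip(bouts, bouts[1:]):
        if b0 < a1:
            raise ValueError(f"bouts ({a0}, {a1}) and ({b0}, {b1}) overlap")
    heights = (
        [float(head_height_cm)] * len(bouts)
        if np.isscalar(head_height_cm)
        else [float(v) for v in head_height_cm]
    )
    if len(heights) != len(bouts):
        raise ValueError("head_height_cm must be scalar or one value per bout")

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    speed = np.zeros(n)
    head_z = np.full(n, baseline_head_height_cm)
    heading = np.zeros(n)
    for (b0, b1, sp), hz in zip(bouts, heights):
        sel = (t >= b0) & (t < b1)
        speed[sel] = sp
        head_z[sel] = hz
        heading[sel] = rng.uniform(0, 2 * math.pi)
    dt = 1.0 / rate
    vx = speed * np.cos(heading)
    vy = speed * np.sin(heading)
    x = np.concatenate([[0.0], np.cumsum(vx[:-1] * dt)])
    y = np.concatenate([[0.0], np.cumsum(vy[:-1] * dt)])
    if jitter_sd > 0:
        x = x + rng.normal(0, jitter_sd, n)
        y = y + rng.normal(0, jitter_sd, n)

    truth = [
        (b0, b1)
        for (b0, b1, sp), hz in zip(bouts, heights)
        if sp > 5.0 and (b1 - b0) > 3.0 and hz < 18.0
    ]
    track = pd.DataFrame({"t_s": t, "x_cm": x, "y_cm": y, "head_z_cm": head_z})
    return track, truth


# ---------------------------------------------------------------------------
# Scene shapes (calibration-accuracy paradigm)
# ---------------------------------------------------------------------------

def gen_scene_shapes(kind: str, **params):
    """Build scene geometry in world-camera visual degrees.

    ``kind`` is one of ``point``, ``line``, ``polygon`` or ``pursuit_path``:

    * ``point(position=(h, v))`` — one point primitive;
    * ``line(endpoints=((h0, v0), (h1, v1)))`` — one segment primitive;
    * ``polygon(vertices=[...], closed=True)`` — consecutive segments;
    * ``pursuit_path(duration, speed, rate=90, seed=0)`` — a timestamped
      point trajectory moving at constant ``speed`` (< 5 deg/s) along a
      smoothly wandering heading, returned as a DataFrame
      (``t_s, x_deg, y_deg``).
    """
    if kind == "point":
        pos = np.asarray(params["position"], dtype=float)
        return [ScenePrimitive(kind="point", coords=pos.reshape(1, 2))]
    if kind == "line":
        ep = np.asarray(params["endpoints"], dtype=float).reshape(2, 2)
        return [ScenePrimitive(kind="segment", coords=ep)]
    if kind == "polygon":
        verts = np.asarray(params["vertices"], dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 2:
            raise ValueError("polygon needs at least 2 vertices")
        closed = params.get("closed", True)
        pairs = list(zip(verts[:-1], verts[1:]))
        if closed:
            pairs.append((verts[-1], verts[0]))
        return [ScenePrimitive(kind="segment", coords=np.stack(p)) for p in pairs]
    if kind == "pursuit_path":
        speed = float(params["speed"])
        if speed >= 5.0:
            raise ValueError(
                f"pursuit speed must stay below 5 deg/s, got {speed}"
            )
        duration = float(params["duration"])
        rate = float(params.get("rate", 90.0))
        rng = np.random.default_rng(params.get("seed", 0))
        n = int(round(duration * rate)) + 1
        dt = 1.0 / rate
        heading = np.cumsum(rng.normal(0.0, 0.3 * math.sqrt(dt), n)) + rng.uniform(0, 2 * math.pi)
        x = np.concatenate([[0.0], np.cumsum(speed * np.cos(heading[:-1]) * dt)])
        y = np.concatenate([[0.0], np.cumsum(speed * np.sin(heading[:-1]) * dt)])
        return pd.DataFrame({"t_s": np.arange(n) * dt, "x_deg": x, "y_deg": y})
    raise ValueError(f"unknown scene kind {kind!r}")


def schedule_scene(
    shapes: Sequence[Sequence[ScenePrimitive]],
    on: float = 3.0,
    off: float = 3.0,
    t_start: float = 0.0,
) -> list[ScenePrimitive]:
    """Assign the draw/dark schedule: each shape is shown for ``on`` seconds
    followed by ``off`` seconds of darkness (defaults 3 s / 3 s)."""
    out: list[ScenePrimitive] = []
    t = t_start
    for shape in shapes:
        for prim in shape:
            out.append(ScenePrimitive(kind=prim.kind, coords=prim.coords, active_interval=(t, t + on)))
        t += on + off
    return out
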