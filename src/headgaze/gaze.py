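"""Stream alignment, gaze composition, velocity, and event segmentation.

In a freely moving animal the eye camera and the head tracker sample on
independent grids sharing a clock origin; alignment interpolates the head stream
onto a uniform grid at the eye-camera rate and composes horizontal gaze as
eye-in-head plus head yaw.  The gaze series is then segmented into gaze
shifts (rapid conjugate eye+head movements whose gaze velocity exceeds a
±200 deg/s threshold, extended outward to the surrounding velocity
zero-crossings so the whole conjugate movement, including the eye-velocity
reversal, lands in one event) and gaze fixations (everything in between,
during which compensatory eye movements cancel head drift).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GazeSeries",
    "ChannelKinematics",
    "GazeEvent",
    "align_streams",
    "compute_velocity",
    "segment_gaze",
    "events_to_frame",
]

GAZE_VELOCITY_THRESHOLD = 200.0  # deg/s, separates gaze shifts from compensatory movements

CHANNELS = ("eye_h", "head_yaw", "gaze_h")


@dataclass
class GazeSeries:
    """Aligned eye/head/gaze time series on a uniform clock.

    All angles are in degrees; ``gaze_h = eye_h + head_yaw`` wherever the
    sample is valid (rightward positive for all three).  ``valid`` flags
    samples where both source streams had data within the alignment gap
    tolerance.
    """

    t: np.ndarray
    eye_h: np.ndarray
    eye_v: np.ndarray
    head_yaw: np.ndarray
    head_pitch: np.ndarray
    gaze_h: np.ndarray
    valid: np.ndarray
    rate: float

    def __post_init__(self):
        n = self.t.size
        for name in ("eye_h", "eye_v", "head_yaw", "head_pitch", "gaze_h", "valid"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name} length mismatch")
        dt = np.diff(self.t)
        if dt.size and (dt <= 0).any():
            i = int(np.argmax(dt <= 0))
            raise ValueError(f"timestamps not strictly increasing at index {i + 1} (t={self.t[i + 1]})")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "eye_h_deg": self.eye_h,
                "eye_v_deg": self.eye_v,
                "head_yaw_deg": self.head_yaw,
                "head_pitch_deg": self.head_pitch,
                "gaze_h_deg": self.gaze_h,
                "valid": self.valid.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GazeSeries":
        t = df["t_s"].to_numpy(float)
        dt = np.median(np.diff(t)) if t.size > 1 else 1.0
        return cls(
            t=t,
            eye_h=df["eye_h_deg"].to_numpy(float),
            eye_v=df["eye_v_deg"].to_numpy(float),
            head_yaw=df["head_yaw_deg"].to_numpy(float),
            head_pitch=df["head_pitch_deg"].to_numpy(float),
            gaze_h=df["gaze_h_deg"].to_numpy(float),
            valid=df["valid"].to_numpy(bool) if "valid" in df else np.ones(t.size, bool),
            rate=1.0 / dt,
        )


@dataclass(frozen=True)
class ChannelKinematics:
    """Kinematic summary of one channel over one event (signed)."""

    amplitude: float  # deg, position change start -> end
    peak_velocity: float  # deg/s, velocity at the in-event |v| extremum
    latency_to_peak: float  # s, from event start to the velocity extremum
    duration: float  # s


@dataclass(frozen=True)
class GazeEvent:
    """One labeled epoch: a gaze shift or a gaze fixation."""

    label: str  # "gaze_shift" | "gaze_fixation"
    t_start: float
    t_end: float
    channels: dict = field(default_factory=dict)  # channel name -> ChannelKinematics

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _nearest_gap(query: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Distance from each query time to the nearest source time."""
    idx = np.searchsorted(source, query)
    left = np.abs(query - source[np.clip(idx - 1, 0, source.size - 1)])
    right = np.abs(source[np.clip(idx, 0, source.size - 1)] - query)
    return np.minimum(left, right)


def _check_monotone(t: np.ndarray, name: str) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{name} timestamps not strictly increasing: first violation at sample {bad[0] + 1} "
            f"(t={t[bad[0] + 1]!r} after t={t[bad[0]]!r})"
        )


def align_streams(
    eye_stream: pd.DataFrame,
    head_stream: pd.DataFrame,
    max_gap: float = 0.05,
    rate: float | None = None,
) -> GazeSeries:
    """Interpolate the head stream onto the eye-camera clock and compose gaze.

    ``eye_stream`` needs columns ``t_s, eye_h_deg, eye_v_deg``;
    ``head_stream`` needs ``t_s, head_yaw_deg, head_pitch_deg``.  Both must
    share a clock origin.  The output grid is uniform at the (inferred or
    given) eye rate over the eye stream's span; any grid sample farther than
    ``max_gap`` seconds from the nearest sample of either stream is marked
    invalid (dropout holes stay holes rather than being bridged).
    """
    te = eye_stream["t_s"].to_numpy(float)
    th = head_stream["t_s"].to_numpy(float)
    _check_monotone(te, "eye stream")
    _check_monotone(th, "head stream")
    if rate is None:
        if te.size < 2:
            raise ValueError("eye stream too short to infer a rate")
        rate = 1.0 / float(np.median(np.diff(te)))
    n = int(round((te[-1] - te[0]) * rate)) + 1
    t = te[0] + np.arange(n) / rate
    # reuse the native timestamps when the eye grid is already uniform, so
    # that identical eye/head grids pass values through bitwise
    if te.size == n and np.abs(te - t).max() < 1e-9:
        t = te

    eye_h = np.interp(t, te, eye_stream["eye_h_deg"].to_numpy(float))
    eye_v = np.interp(t, te, eye_stream["eye_v_deg"].to_numpy(float))
    head_yaw = np.interp(t, th, head_stream["head_yaw_deg"].to_numpy(float))
    head_pitch = np.interp(t, th, head_stream["head_pitch_deg"].to_numpy(float))
    valid = (_nearest_gap(t, te) <= max_gap) & (_nearest_gap(t, th) <= max_gap)
    valid &= (t >= th[0] - max_gap) & (t <= th[-1] + max_gap)

    gaze_h = np.where(valid, eye_h + head_yaw, np.nan)
    return GazeSeries(
        t=t,
        eye_h=eye_h,
        eye_v=eye_v,
        head_yaw=head_yaw,
        head_pitch=head_pitch,
        gaze_h=gaze_h,
        valid=valid,
        rate=float(rate),
    )


def compute_velocity(
    series: GazeSeries, channel: str = "gaze_h", smoothing_window: int = 5
) -> np.ndarray:
    """Velocity (deg/s) of one channel: moving average, then central difference.

    The channel is smoothed with a centered moving average of
    ``smoothing_window`` samples (odd, >= 1), differentiated with central
    differences (one-sided at the endpoints).  Samples whose stencil touches
    an invalid sample are returned as NaN.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    x = getattr(series, channel).astype(float)
    n = x.size
    if smoothing_window > n:
        raise ValueError(f"smoothing_window {smoothing_window} exceeds series length {n}")
    if n < 2:
        raise ValueError("series too short to differentiate")
    xf = np.where(series.valid, x, 0.0)
    if smoothing_window > 1:
        xs = ndimage.uniform_filter1d(xf, size=smoothing_window, mode="nearest")
    else:
        xs = xf
    dt = 1.0 / series.rate
    v = np.empty(n)
    v[1:-1] = (xs[2:] - xs[:-2]) / (2 * dt)
    v[0] = (xs[1] - xs[0]) / dt
    v[-1] = (xs[-1] - xs[-2]) / dt
    # invalidity propagates through the smoothing + difference stencil
    invalid = ~series.valid
    reach = smoothing_window // 2 + 1
    invalid = ndimage.binary_dilation(invalid, iterations=reach)
    v[invalid] = np.nan
    return v


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end] index pairs (inclusive) of True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    return list(zip(starts, ends))


def _extend_to_zero_crossing(v: np.ndarray, s: int, e: int, lo: int, hi: int) -> tuple[int, int]:
    """Widen [s, e] while velocity keeps the sign it has inside the run."""
    sign = np.sign(v[s + int(np.nanargmax(np.abs(v[s : e + 1])))])
    while s - 1 >= lo and np.isfinite(v[s - 1]) and v[s - 1] * sign > 0:
        s -= 1
    while e + 1 <= hi and np.isfinite(v[e + 1]) and v[e + 1] * sign > 0:
        e += 1
    return s, e


def _channel_kinematics(series: GazeSeries, vel: dict, s: int, e: int) -> dict:
    dt = 1.0 / series.rate
    out = {}
    for ch in CHANNELS:
        x = getattr(series, ch)
        v = vel[ch][s : e + 1]
        finite = np.isfinite(v)
        if finite.any():
            k = int(np.nanargmax(np.abs(v)))
            peak = float(v[k])
            latency = k * dt
        else:
            peak, latency = float("nan"), float("nan")
        out[ch] = ChannelKinematics(
            amplitude=float(x[e] - x[s]),
            peak_velocity=peak,
            latency_to_peak=latency,
            duration=(e - s) * dt,
        )
    return out


def segment_gaze(
    series: GazeSeries,
    v_threshold: float = GAZE_VELOCITY_THRESHOLD,
    min_shift_duration: float = 0.02,
    min_fixation_duration: float = 0.05,
    smoothing_window: int = 3,
) -> list[GazeEvent]:
    """Split a gaze series into gaze shifts and gaze fixations.

    Contiguous runs where |gaze velocity| exceeds ``v_threshold`` (default
    the ±200 deg/s criterion), extended outward to the nearest gaze-velocity
    zero-crossing and lasting at least ``min_shift_duration``, become gaze
    shifts; the complement becomes gaze fixations.  Complement fragments
    shorter than ``min_fixation_duration`` are absorbed into the preceding
    shift so that events tile each valid stretch of the series without
    overlap.  Per-event kinematics (amplitude, peak velocity, latency to
    peak, duration) are reported for the eye, head and gaze channels.
    """
    if v_threshold <= 0 or min_shift_duration < 0 or min_fixation_duration < 0:
        raise ValueError("thresholds and minimum durations must be positive")
    if not series.valid.any():
        warnings.warn("series entirely invalid; no events", stacklevel=2)
        return []
    vel = {ch: compute_velocity(series, ch, smoothing_window) for ch in CHANNELS}
    vg = vel["gaze_h"]
    dt = 1.0 / series.rate
    events: list[GazeEvent] = []

    for lo, hi in _runs(series.valid):
        above = np.zeros(series.t.size, dtype=bool)
        seg = slice(lo, hi + 1)
        above[seg] = np.abs(np.where(np.isfinite(vg[seg]), vg[seg], 0.0)) > v_threshold
        shifts: list[tuple[int, int]] = []
        for s, e in _runs(above):
            s, e = _extend_to_zero_crossing(vg, s, e, lo, hi)
            if shifts and s <= shifts[-1][1] + 1:
                shifts[-1] = (shifts[-1][0], max(e, shifts[-1][1]))
            else:
                shifts.append((s, e))
        shifts = [(s, e) for s, e in shifts if (e - s) * dt >= min_shift_duration]

        # tile the run: fixations fill the gaps; short fragments are absorbed
        intervals: list[tuple[int, int, str]] = []
        cursor = lo
        for s, e in shifts:
            if s > cursor:
                if (s - cursor) * dt >= min_fixation_duration or not intervals:
                    intervals.append((cursor, s - 1, "gaze_fixation"))
                else:
                    ps, _, plabel = intervals[-1]
                    intervals[-1] = (ps, s - 1, plabel)
            intervals.append((s, e, "gaze_shift"))
            cursor = e + 1
        if cursor <= hi:
            if (hi - cursor) * dt >= min_fixation_duration or not intervals:
                intervals.append((cursor, hi, "gaze_fixation"))
            else:
                ps, _, plabel = intervals[-1]
                intervals[-1] = (ps, hi, plabel)

        for s, e, label in intervals:
            if e <= s:
                continue
            events.append(
                GazeEvent(
                    label=label,
                    t_start=float(series.t[s]),
                    t_end=float(series.t[e]),
                    channels=_channel_kinematics(series, vel, s, e),
                )
            )
    return events


def events_to_frame(events: list[GazeEvent]) -> pd.DataFrame:
    """Flatten events into a DataFrame (one row per event, channels wide)."""
    rows = []
    for ev in events:
        row = {"label": ev.label, "t_start_s": ev.t_start, "t_end_s": ev.t_end,
               "duration_s": ev.duration}
        for ch, kin in ev.channels.items():
            row[f"{ch}_amplitude_deg"] = kin.amplitude
            row[f"{ch}_peak_velocity_dps"] = kin.peak_velocity
            row[f"{ch}_latency_to_peak_s"] = kin.latency_to_peak
        rows.append(row)
    return pd.DataFrame(rows)
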