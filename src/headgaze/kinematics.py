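"""Headline gaze-kinematics statistics.

Main sequence of gaze shifts (peak velocity, latency and duration versus
gaze amplitude, with a saturating fit for the eye-velocity component), VOR
gain from the negative regression of eye on head velocity during stable
fixations, rms stabilization of gaze and head within fixation epochs,
approximate entropy of gaze/eye time series, locomotion classification from
body-speed and head-height rules, and per-behavioral-state gaze-shift
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal, stats

from headgaze.gaze import GazeEvent, GazeSeries, compute_velocity

__all__ = [
    "BehaviorEpoch",
    "VorGainResult",
    "main_sequence",
    "vor_gain",
    "rms_stabilization",
    "approximate_entropy",
    "classify_locomotion",
    "shift_statistics",
    "occupancy_map",
    "eye_position_distributions",
    "stability_report",
]

SPEED_THRESHOLD_CM_S = 5.0
MIN_LOCOMOTION_DURATION_S = 3.0
MAX_LOCOMOTION_HEAD_HEIGHT_CM = 18.0
LOWPASS_CUTOFF_HZ = 0.2


@dataclass(frozen=True)
class BehaviorEpoch:
    """A locomotion or stationary interval; epochs tile the session."""

    label: str  # "locomotion" | "stationary"
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class VorGainResult:
    """VOR gain with its regression standard error and sample count."""

    gain: float
    se: float
    n: int


# ---------------------------------------------------------------------------
# Main sequence
# ---------------------------------------------------------------------------

def _hinge_fit(amplitude: np.ndarray, velocity: np.ndarray, knee_grid: np.ndarray):
    """Least-squares fit of v = plateau * min(a, knee) / knee over a knee grid."""
    best = (np.inf, np.nan, np.nan)
    for knee in knee_grid:
        w = np.minimum(amplitude, knee) / knee
        denom = float(w @ w)
        if denom == 0:
            continue
        vp = float(w @ velocity) / denom
        sse = float(np.sum((velocity - vp * w) ** 2))
        if sse < best[0]:
            best = (sse, vp, float(knee))
    return {"plateau_dps": best[1], "knee_deg": best[2], "sse": best[0]}


def main_sequence(
    events: Sequence[GazeEvent],
    bin_width: float = 5.0,
    knee_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-shift kinematics table, amplitude-binned medians, and eye-velocity fit.

    Rows are gaze shifts only; every quantity is rectified by the shift
    direction (so a channel moving with the shift is positive).  The
    saturating fit models eye peak velocity as linear in gaze amplitude up
    to a knee and flat at a plateau beyond, fitted by least squares over a
    knee grid; it mirrors the empirical saturation of the eye component
    (the head component keeps growing for the largest shifts).

    Returns ``(table, binned, fit)``; both frames are empty and the fit
    entries NaN when there are no shifts.
    """
    shifts = [ev for ev in events if ev.label == "gaze_shift"]
    if not shifts:
        return pd.DataFrame(), pd.DataFrame(), {"plateau_dps": float("nan"), "knee_deg": float("nan")}
    rows = []
    for ev in shifts:
        gaze = ev.channels["gaze_h"]
        sign = 1.0 if gaze.amplitude >= 0 else -1.0
        row = {
            "t_start_s": ev.t_start,
            "gaze_amplitude_deg": abs(gaze.amplitude),
            "duration_s": ev.duration,
        }
        for ch in ("eye_h", "head_yaw", "gaze_h"):
            kin = ev.channels[ch]
            row[f"{ch}_amplitude_deg"] = sign * kin.amplitude
            row[f"{ch}_peak_velocity_dps"] = sign * kin.peak_velocity
            row[f"{ch}_latency_to_peak_s"] = kin.latency_to_peak
        rows.append(row)
    table = pd.DataFrame(rows)

    amp = table["gaze_amplitude_deg"].to_numpy()
    bins = np.arange(0.0, amp.max() + bin_width, bin_width)
    table["_bin"] = pd.cut(amp, bins)
    binned = table.groupby("_bin", observed=True).median(numeric_only=True)
    binned["n"] = table.groupby("_bin", observed=True).size()
    table = table.drop(columns="_bin")

    if knee_grid is None:
        knee_grid = np.arange(2.0, min(40.0, max(4.0, amp.max())) + 0.25, 0.25)
    fit = _hinge_fit(amp, table["eye_h_peak_velocity_dps"].to_numpy(), np.asarray(knee_grid))
    return table, binned, fit


# ---------------------------------------------------------------------------
# VOR gain
# ---------------------------------------------------------------------------

def vor_gain(
    series: GazeSeries,
    fixation_epochs: Sequence[tuple[float, float]],
    smoothing_window: int = 3,
    min_samples: int = 30,
) -> VorGainResult:
    """VOR gain from eye-vs-head velocity regression during stable fixations.

    The compensatory (vestibulo-ocular) eye velocity correlates negatively
    with head velocity during gaze fixations; the gain is the negated
    least-squares slope of eye velocity on head velocity over the pooled
    fixation samples.  Samples whose velocity stencil crosses an epoch
    boundary are dropped so shift transients never leak in.
    """
    ve = compute_velocity(series, "eye_h", smoothing_window)
    vh = compute_velocity(series, "head_yaw", smoothing_window)
    margin = (smoothing_window // 2 + 1) / series.rate
    sel = np.zeros(series.t.size, dtype=bool)
    for t0, t1 in fixation_epochs:
        sel |= (series.t >= t0 + margin) & (series.t <= t1 - margin)
    sel &= np.isfinite(ve) & np.isfinite(vh)
    n = int(sel.sum())
    if n < min_samples:
        raise ValueError(f"only {n} pooled fixation samples (< {min_samples})")
    x, y = vh[sel], ve[sel]
    if np.ptp(x) == 0:
        raise ValueError("head velocity has zero variance: VOR gain unidentifiable")
    res = stats.linregress(x, y)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return VorGainResult(gain=float(-res.slope), se=se, n=n)


# ---------------------------------------------------------------------------
# rms stabilization
# ---------------------------------------------------------------------------

def rms_stabilization(
    series: GazeSeries,
    fixation_epochs: Sequence[tuple[float, float]],
    channel: str = "gaze_h",
    behavior_epochs: Sequence[BehaviorEpoch] | None = None,
    min_samples: int = 3,
) -> tuple[list[float], dict]:
    """Per-fixation rms deviation about the epoch mean, with pooled summary.

    Smaller values mean better stabilization.  When ``behavior_epochs`` are
    supplied, fixations are grouped by the behavioral state containing
    their midpoint and the summary also reports per-state pooled means.
    """
    x = getattr(series, channel)
    per_epoch: list[float] = []
    mids: list[float] = []
    for t0, t1 in fixation_epochs:
        m = (series.t >= t0) & (series.t <= t1) & series.valid
        seg = x[m]
        if seg.size < min_samples:
            warnings.warn(
                f"fixation epoch ({t0:.3f}, {t1:.3f}) has {seg.size} < {min_samples} samples; skipped",
                stacklevel=2,
            )
            continue
        per_epoch.append(float(np.sqrt(np.mean((seg - seg.mean()) ** 2))))
        mids.append(0.5 * (t0 + t1))
    summary = {
        "channel": channel,
        "pooled_rms_deg": float(np.mean(per_epoch)) if per_epoch else float("nan"),
        "n_epochs": len(per_epoch),
    }
    if behavior_epochs is not None:
        by_state: dict[str, list[float]] = {}
        for rms, mid in zip(per_epoch, mids):
            state = _state_at(behavior_epochs, mid)
            if state is not None:
                by_state.setdefault(state, []).append(rms)
        summary["by_state"] = {
            state: {"pooled_rms_deg": float(np.mean(v)), "n_epochs": len(v)}
            for state, v in by_state.items()
        }
    return per_epoch, summary


def _state_at(behavior_epochs: Sequence[BehaviorEpoch], t: float) -> str | None:
    for ep in behavior_epochs:
        if ep.t_start <= t <= ep.t_end:
            return ep.label
    return None


# ---------------------------------------------------------------------------
# Approximate entropy
# ---------------------------------------------------------------------------

def _phi(x: np.ndarray, m: int, r_abs: float, block: int = 256) -> float:
    emb = sliding_window_view(x, m)
    n = emb.shape[0]
    logs = np.empty(n)
    for start in range(0, n, block):
        chunk = emb[start : start + block]
        d = np.abs(chunk[:, None, :] - emb[None, :, :]).max(axis=2)
        logs[start : start + block] = np.log(np.count_nonzero(d <= r_abs, axis=1) / n)
    return float(np.mean(logs))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Approximate entropy (ApEn) of a time series.

    ApEn(m, r) = Phi_m(r) - Phi_{m+1}(r), where Phi_m is the mean log
    fraction of length-m templates lying within Chebyshev distance
    ``r * SD(x)`` of each template (self-matches included).  Low values mean
    a predictable, self-similar series; a constant series has ApEn 0.
    Defaults m=2, r=0.2 are the field-standard choices.
    """
    x = np.asarray(x, dtype=float).ravel()
    if r <= 0:
        raise ValueError("tolerance r must be > 0")
    if m < 1:
        raise ValueError("embedding length m must be >= 1")
    if x.size < 10 * m:
        raise ValueError(f"series length {x.size} < 10*m = {10 * m}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0  # every template matches every other at any tolerance
    r_abs = r * sd
    return _phi(x, m, r_abs) - _phi(x, m + 1, r_abs)


# ---------------------------------------------------------------------------
# Locomotion classification
# ---------------------------------------------------------------------------

def classify_locomotion(
    body_positions: np.ndarray,
    head_heights: np.ndarray,
    rate: float,
    speed_threshold: float = SPEED_THRESHOLD_CM_S,
    min_duration: float = MIN_LOCOMOTION_DURATION_S,
    max_head_height: float = MAX_LOCOMOTION_HEAD_HEIGHT_CM,
    lowpass_cutoff: float = LOWPASS_CUTOFF_HZ,
) -> list[BehaviorEpoch]:
    """Classify each moment as locomotion or stationary from body/head tracks.

    Locomotion requires all three rules simultaneously: body speed (after a
    zero-phase 2nd-order low-pass at 0.2 Hz) above 5 cm/s, epoch duration
    above 3 s, and head height below 18 cm.  Everything else is stationary;
    the returned epochs tile the session.
    """
    xy = np.asarray(body_positions, dtype=float).reshape(-1, 2)
    hz = np.asarray(head_heights, dtype=float).ravel()
    if xy.shape[0] != hz.size:
        raise ValueError(
            f"body track ({xy.shape[0]} samples) and head track ({hz.size}) timestamps mismatch"
        )
    n = xy.shape[0]
    t = np.arange(n) / rate
    if n < 13:
        raise ValueError("track too short to filter and classify")
    v = np.gradient(xy, 1.0 / rate, axis=0)
    speed = np.hypot(v[:, 0], v[:, 1])
    b, a = signal.butter(2, lowpass_cutoff / (rate / 2.0))
    speed_f = signal.filtfilt(b, a, speed)

    moving = (speed_f > speed_threshold) & (hz < max_head_height)
    epochs: list[BehaviorEpoch] = []
    cursor = 0
    padded = np.concatenate([[False], moving, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    for s, e in zip(starts, ends):
        if (e - s) / rate <= min_duration:
            continue  # too brief: stays stationary
        if s > cursor:
            epochs.append(BehaviorEpoch("stationary", t[cursor], t[s]))
        epochs.append(BehaviorEpoch("locomotion", t[s], t[e]))
        cursor = e
    if cursor < n - 1 or not epochs:
        epochs.append(BehaviorEpoch("stationary", t[cursor], t[n - 1]))
    return epochs


# ---------------------------------------------------------------------------
# Per-state shift statistics
# ---------------------------------------------------------------------------

def shift_statistics(
    events: Sequence[GazeEvent],
    behavior_epochs: Sequence[BehaviorEpoch],
) -> dict:
    """Gaze-shift rate, amplitude and peak-speed distributions per state.

    Each shift is assigned to the behavioral state containing its midpoint;
    the rate is shifts per second of state time.  Distributions are
    summarized by median and interquartile range, and the two states are
    contrasted with a Wilcoxon rank-sum test (no multiple-testing
    correction; one test per quantity).
    """
    durations: dict[str, float] = {}
    for ep in behavior_epochs:
        if ep.duration > 0:
            durations[ep.label] = durations.get(ep.label, 0.0) + ep.duration
    samples: dict[str, dict[str, list[float]]] = {
        s: {"amplitude": [], "peak_speed": []} for s in durations
    }
    for ev in events:
        if ev.label != "gaze_shift":
            continue
        state = _state_at(behavior_epochs, 0.5 * (ev.t_start + ev.t_end))
        if state is None or state not in samples:
            continue
        gaze = ev.channels["gaze_h"]
        samples[state]["amplitude"].append(abs(gaze.amplitude))
        samples[state]["peak_speed"].append(abs(gaze.peak_velocity))
    out: dict = {"by_state": {}}
    for state, vals in samples.items():
        amp = np.asarray(vals["amplitude"])
        spd = np.asarray(vals["peak_speed"])
        out["by_state"][state] = {
            "n_shifts": int(amp.size),
            "rate_per_s": float(amp.size / durations[state]),
            "median_amplitude_deg": float(np.median(amp)) if amp.size else float("nan"),
            "iqr_amplitude_deg": float(np.subtract(*np.percentile(amp, [75, 25]))) if amp.size else float("nan"),
            "median_peak_speed_dps": float(np.median(spd)) if spd.size else float("nan"),
            "iqr_peak_speed_dps": float(np.subtract(*np.percentile(spd, [75, 25]))) if spd.size else float("nan"),
        }
    states = sorted(samples)
    if len(states) == 2:
        a, b = states
        tests = {}
        for key in ("amplitude", "peak_speed"):
            xa, xb = samples[a][key], samples[b][key]
            if len(xa) and len(xb):
                stat, p = stats.ranksums(xa, xb)
                tests[key] = {"statistic": float(stat), "p_value": float(p)}
        out["rank_sum_tests"] = tests
    return out


# ---------------------------------------------------------------------------
# Occupancy map and eye-position distributions
# ---------------------------------------------------------------------------

def occupancy_map(
    times: np.ndarray,
    body_positions: np.ndarray,
    bin_size: float,
    behavior_epochs: Sequence[BehaviorEpoch],
    arena_bounds: tuple[tuple[float, float], tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[np.ndarray]]:
    """Stationary-occupancy histogram plus locomotion path polylines.

    Stationary samples are binned on a ``bin_size``-cm grid over the arena
    (samples outside the bounds fall in the edge bins, with a warning);
    locomotion samples are returned as ordered per-epoch polylines.
    Returns ``(grid, x_edges, y_edges, paths)``; the grid total equals the
    number of stationary samples.
    """
    t = np.asarray(times, dtype=float)
    xy = np.asarray(body_positions, dtype=float).reshape(-1, 2)
    (x0, x1), (y0, y1) = arena_bounds
    x_edges = np.arange(x0, x1 + bin_size, bin_size)
    y_edges = np.arange(y0, y1 + bin_size, bin_size)
    stationary = np.zeros(t.size, dtype=bool)
    assigned = np.zeros(t.size, dtype=bool)
    paths: list[np.ndarray] = []
    for ep in behavior_epochs:
        m = (t >= ep.t_start) & (t <= ep.t_end) & ~assigned
        assigned |= m
        if ep.label == "stationary":
            stationary |= m
        elif m.any():
            paths.append(xy[m])
    pts = xy[stationary]
    n_outside = int(np.sum((pts[:, 0] < x0) | (pts[:, 0] > x1) | (pts[:, 1] < y0) | (pts[:, 1] > y1)))
    if n_outside:
        warnings.warn(f"{n_outside} samples outside arena bounds counted in edge bins", stacklevel=2)
    clipped_x = np.clip(pts[:, 0], x0, np.nextafter(x1, x0))
    clipped_y = np.clip(pts[:, 1], y0, np.nextafter(y1, y0))
    grid, _, _ = np.histogram2d(clipped_x, clipped_y, bins=(x_edges, y_edges))
    return grid, x_edges, y_edges, paths


def eye_position_distributions(
    series: GazeSeries,
    events: Sequence[GazeEvent],
    bins: int = 40,
    min_valid: int = 100,
) -> dict:
    """Eye-in-head position histograms split by fixation vs. shift.

    For each channel (horizontal/vertical eye position) and each event
    label, reports the histogram and the 2 SD span (the ± value such that
    two standard deviations of the data fall within it).  The two splits
    partition the valid samples.
    """
    if int(series.valid.sum()) < min_valid:
        raise ValueError(f"need >= {min_valid} valid samples, have {int(series.valid.sum())}")
    label = np.full(series.t.size, "", dtype=object)
    for ev in events:
        m = (series.t >= ev.t_start) & (series.t <= ev.t_end) & (label == "")
        label[m] = "shift" if ev.label == "gaze_shift" else "fixation"
    out: dict = {}
    for ch, col in (("eye_h", series.eye_h), ("eye_v", series.eye_v)):
        out[ch] = {}
        for split in ("fixation", "shift"):
            x = col[series.valid & (label == split)]
            counts, edges = np.histogram(x, bins=bins)
            out[ch][split] = {
                "n": int(x.size),
                "span_2sd_deg": float(2.0 * np.std(x)) if x.size else 0.0,
                "hist_counts": counts,
                "hist_edges": edges,
            }
    return out


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

def stability_report(
    series: GazeSeries,
    events: Sequence[GazeEvent],
    behavior_epochs: Sequence[BehaviorEpoch] | None = None,
    apen_m: int = 2,
    apen_r: float = 0.2,
    apen_on: str = "position",
) -> dict:
    """Assemble the per-state stability summary.

    Reports, per behavioral state (or pooled when no epochs are supplied):
    gaze and head rms during fixations, VOR gain with standard error,
    gaze-shift rate / median amplitude / median peak speed, and approximate
    entropy of the eye and gaze channels (computed on position or velocity
    series, declared in the output).
    """
    fixations = [(ev.t_start, ev.t_end) for ev in events if ev.label == "gaze_fixation"]
    report: dict = {"apen_params": {"m": apen_m, "r": apen_r, "on": apen_on}}
    _, gaze_rms = rms_stabilization(series, fixations, "gaze_h", behavior_epochs)
    _, head_rms = rms_stabilization(series, fixations, "head_yaw", behavior_epochs)
    report["gaze_rms"] = gaze_rms
    report["head_rms"] = head_rms
    try:
        vg = vor_gain(series, fixations)
        report["vor_gain"] = {"gain": vg.gain, "se": vg.se, "n": vg.n}
    except ValueError as exc:
        report["vor_gain"] = {"error": str(exc)}
    if behavior_epochs is not None:
        report["shift_statistics"] = shift_statistics(events, behavior_epochs)
    apen: dict = {}
    for ch in ("eye_h", "gaze_h"):
        x = getattr(series, ch)[series.valid]
        if apen_on == "velocity":
            x = np.diff(x) * series.rate
        if x.size >= 10 * apen_m:
            apen[ch] = approximate_entropy(x, apen_m, apen_r)
    report["approximate_entropy"] = apen
    return report
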