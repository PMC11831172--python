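"""Pupil-to-world calibration and gaze-accuracy estimation.

Calibration maps the pupil center in eye-camera pixels to world-camera
visual degrees with an independent affine transform per axis
(``deg = gain * px + offset``) — the same family a human operator adjusts
through scaling and offset sliders.  Accuracy against known scene geometry
is quantified by the nearest-feature error: for every gaze sample the
distance to the closest active point or line segment, with samples farther
than a registration bound (default 3.5 visual degrees) treated as not
looking at the feature and excluded from the accuracy summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel",
    "ScenePrimitive",
    "fit_calibration",
    "apply_calibration",
    "estimate_error",
    "rms_fixation_precision",
]

REGISTRATION_BOUND_DEG = 3.5  # max nearest-feature distance to count as "looking at" it


@dataclass(frozen=True)
class CalibrationModel:
    """Per-axis affine map from pupil pixels to visual degrees."""

    gain_h: float  # degrees per pixel, horizontal
    gain_v: float
    offset_h: float  # degrees
    offset_v: float
    fit_residual_rms: float = 0.0
    n_points: int = 0

    def __post_init__(self):
        if self.gain_h == 0 or self.gain_v == 0:
            raise ValueError("calibration gains must be nonzero")


@dataclass(frozen=True)
class ScenePrimitive:
    """A drawn scene feature: a point or a line segment, in visual degrees.

    ``coords`` has shape (1, 2) for a point or (2, 2) for a segment
    (rows are (h, v) coordinates).  ``active_interval`` is the (t_on, t_off)
    window during which the feature is drawn; ``None`` means always active.
    """

    kind: str  # "point" | "segment"
    coords: np.ndarray
    active_interval: tuple[float, float] | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if self.kind == "point" and coords.shape != (1, 2):
            raise ValueError("point primitive needs coords of shape (1, 2)")
        if self.kind == "segment":
            if coords.shape != (2, 2):
                raise ValueError("segment primitive needs coords of shape (2, 2)")
            if np.allclose(coords[0], coords[1]):
                raise ValueError("segment endpoints must be distinct")
        if self.kind not in ("point", "segment"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if self.active_interval is not None and not self.active_interval[0] < self.active_interval[1]:
            raise ValueError("active_interval must satisfy t_on < t_off")


def fit_calibration(
    pupil_points: np.ndarray, target_points: np.ndarray
) -> CalibrationModel:
    """Least-squares fit of per-axis gain and offset.

    ``pupil_points`` (n, 2) are pupil centers in pixels (h, v);
    ``target_points`` (n, 2) are the matching calibration-target positions
    in visual degrees.  Each axis is fitted independently.
    """
    px = np.asarray(pupil_points, dtype=float)
    deg = np.asarray(target_points, dtype=float)
    if px.shape != deg.shape or px.ndim != 2 or px.shape[1] != 2:
        raise ValueError("pupil_points and target_points must both have shape (n, 2)")
    if px.shape[0] < 2:
        raise ValueError("need at least 2 calibration points")
    gains, offsets, residuals = [], [], []
    for axis, name in ((0, "horizontal"), (1, "vertical")):
        x, y = px[:, axis], deg[:, axis]
        if np.ptp(x) == 0:
            raise ValueError(f"all pupil points identical on the {name} axis: gain unidentifiable")
        gain, offset = np.polyfit(x, y, 1)
        gains.append(gain)
        offsets.append(offset)
        residuals.append(y - (gain * x + offset))
    rms = float(np.sqrt(np.mean(np.concatenate(residuals) ** 2)))
    return CalibrationModel(
        gain_h=float(gains[0]),
        gain_v=float(gains[1]),
        offset_h=float(offsets[0]),
        offset_v=float(offsets[1]),
        fit_residual_rms=rms,
        n_points=px.shape[0],
    )


def apply_calibration(model: CalibrationModel, estimate) -> tuple[float, float] | None:
    """Map a pupil estimate (or a raw (h, v) pixel pair) into visual degrees.

    Invalid pupil estimates map to ``None`` (a missing gaze sample).
    """
    if hasattr(estimate, "valid"):
        if not estimate.valid:
            return None
        # PupilEstimate centers are (row, col) = (vertical, horizontal) pixels
        px_h, px_v = estimate.center[1], estimate.center[0]
    else:
        px_h, px_v = float(estimate[0]), float(estimate[1])
    return (model.gain_h * px_h + model.offset_h, model.gain_v * px_v + model.offset_v)


def apply_calibration_array(model: CalibrationModel, centers: np.ndarray) -> np.ndarray:
    """Vectorized affine map of (n, 2) pupil (h, v) pixel pairs to degrees."""
    c = np.asarray(centers, dtype=float)
    return np.column_stack(
        [model.gain_h * c[:, 0] + model.offset_h, model.gain_v * c[:, 1] + model.offset_v]
    )


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to segment [a, b] (clamped projection)."""
    ab = b - a
    denom = float(ab @ ab)
    tproj = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a + tproj[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


def estimate_error(
    times: np.ndarray,
    gaze: np.ndarray,
    scene: Sequence[ScenePrimitive],
    bound: float = REGISTRATION_BOUND_DEG,
) -> tuple[pd.DataFrame, dict]:
    """Nearest-feature gaze error against scheduled scene geometry.

    For each gaze sample, the error is the minimum Euclidean distance to any
    primitive active at that time (point-to-point, or point-to-segment with
    the projection clamped to the endpoints).  Samples during dark periods
    (no active primitive) are excluded; samples farther than ``bound`` from
    every active feature are recorded but not registered as looking at a
    feature.  The summary reports the median error over registered samples.

    Returns ``(samples, summary)``: a DataFrame with columns
    ``t_s, gaze_h_deg, gaze_v_deg, nearest_distance_deg, registered, in_dark``
    and a dict with ``median_error_deg, n_registered, n_excluded_dark,
    n_unregistered, bound_deg``.
    """
    if not scene:
        raise ValueError("scene must contain at least one primitive")
    t = np.asarray(times, dtype=float)
    g = np.asarray(gaze, dtype=float).reshape(-1, 2)
    dist = np.full(t.size, np.nan)
    in_dark = np.ones(t.size, dtype=bool)
    for prim in scene:
        if prim.active_interval is None:
            active = np.ones(t.size, dtype=bool)
        else:
            t_on, t_off = prim.active_interval
            active = (t > t_on) & (t < t_off)  # boundary samples excluded
        if not active.any():
            continue
        pts = g[active]
        if prim.kind == "point":
            d = np.linalg.norm(pts - prim.coords[0], axis=1)
        else:
            d = _point_segment_distance(pts, prim.coords[0], prim.coords[1])
        cur = dist[active]
        dist[active] = np.where(np.isnan(cur), d, np.minimum(cur, d))
        in_dark[active] = False
    registered = ~in_dark & (dist <= bound)
    samples = pd.DataFrame(
        {
            "t_s": t,
            "gaze_h_deg": g[:, 0],
            "gaze_v_deg": g[:, 1],
            "nearest_distance_deg": dist,
            "registered": registered,
            "in_dark": in_dark,
        }
    )
    reg_d = dist[registered]
    summary = {
        "median_error_deg": float(np.median(reg_d)) if reg_d.size else float("nan"),
        "n_registered": int(registered.sum()),
        "n_excluded_dark": int(in_dark.sum()),
        "n_unregistered": int((~in_dark & ~registered).sum()),
        "bound_deg": float(bound),
    }
    return samples, summary


def rms_fixation_precision(
    times: np.ndarray,
    positions: np.ndarray,
    fixation_epochs: Sequence[tuple[float, float]],
    min_samples: int = 3,
) -> tuple[list[float], float]:
    """Root-mean-square deviation of position about its mean, per fixation.

    ``positions`` is a 1-D series (e.g. horizontal eye position in degrees).
    Epochs with fewer than ``min_samples`` samples are skipped with a
    warning.  Returns (per-epoch rms list, pooled mean across epochs).
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(positions, dtype=float)
    out: list[float] = []
    for t0, t1 in fixation_epochs:
        seg = x[(t >= t0) & (t <= t1)]
        if seg.size < min_samples:
            warnings.warn(
                f"fixation epoch ({t0:.3f}, {t1:.3f}) has {seg.size} < {min_samples} samples; skipped",
                stacklevel=2,
            )
            continue
        out.append(float(np.sqrt(np.mean((seg - seg.mean()) ** 2))))
    pooled = float(np.mean(out)) if out else float("nan")
    return out, pooled
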