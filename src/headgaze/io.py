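"""File formats, configuration and the end-to-end pipeline runner.

Interchange formats are deliberately plain: CSV with named headers for all
time series and event tables (column order never matters), PNG directories
with a CSV timestamp index for eye-frame stacks, YAML for configuration.
All angles are degrees, time is seconds, positions are centimeters.  Every
run writes a manifest carrying the digest of the exact configuration used,
so outputs are traceable and reruns are byte-comparable.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from headgaze import calibrate, gaze, kinematics, pupil, synthdata

logger = logging.getLogger(__name__)

__all__ = [
    "TABLE_SCHEMAS",
    "read_table",
    "write_table",
    "read_frames",
    "write_frames",
    "read_config",
    "default_config",
    "config_digest",
    "run_pipeline",
]

# required columns per table kind; extra columns pass through with a warning
TABLE_SCHEMAS = {
    "eye_series": ["t_s", "eye_h_deg", "eye_v_deg"],
    "head_series": ["t_s", "head_yaw_deg", "head_pitch_deg"],
    "gaze_series": ["t_s", "eye_h_deg", "eye_v_deg", "head_yaw_deg", "head_pitch_deg", "gaze_h_deg", "valid"],
    "events": ["label", "t_start_s", "t_end_s"],
    "pupil_estimates": ["t_s", "center_row_px", "center_col_px", "valid"],
    "calibration_points": ["pupil_px_h", "pupil_px_v", "target_deg_h", "target_deg_v"],
    "body_track": ["t_s", "x_cm", "y_cm", "head_z_cm"],
}

FLOAT_FORMAT = "%.9f"  # preserves timestamps to 1e-6 s and angles to 1e-6 deg


def write_table(df: pd.DataFrame, path, kind: str | None = None) -> Path:
    """Write a CSV table, checking the column contract when ``kind`` is given."""
    if kind is not None:
        missing = [c for c in TABLE_SCHEMAS[kind] if c not in df.columns]
        if missing:
            raise ValueError(f"{kind} table missing required columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_table(path, kind: str | None = None) -> pd.DataFrame:
    """Read a CSV table; column order is irrelevant, names are the contract."""
    df = pd.read_csv(path)
    if kind is not None:
        required = TABLE_SCHEMAS[kind]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns for {kind}: {missing}")
        unknown = [c for c in df.columns if c not in required]
        if unknown:
            warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
    return df


def write_frames(images: np.ndarray, timestamps: np.ndarray, directory) -> Path:
    """Write a frame stack as numbered PNGs plus an ``index.csv`` timestamp table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, img in enumerate(images):
        name = f"frame_{i:06d}.png"
        iio.imwrite(directory / name, np.clip(img, 0, 255).astype(np.uint8))
        names.append(name)
    index = pd.DataFrame({"frame": np.arange(len(names)), "t_s": timestamps, "filename": names})
    index.to_csv(directory / "index.csv", index=False, float_format=FLOAT_FORMAT)
    return directory


def read_frames(directory) -> tuple[np.ndarray, np.ndarray]:
    """Read a PNG frame stack written by :func:`write_frames`."""
    directory = Path(directory)
    index = pd.read_csv(directory / "index.csv")
    if "t_s" not in index.columns or "filename" not in index.columns:
        raise ValueError(f"{directory}/index.csv must have t_s and filename columns")
    images = np.stack([iio.imread(directory / name) for name in index["filename"]])
    return images.astype(float), index["t_s"].to_numpy(float)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Demo pipeline configuration: everything synthetic, fixed seeds."""
    return {
        "seed": 0,
        "simulate": {
            "duration_s": 60.0,
            "eye_rate_hz": 90.0,
            "head_rate_hz": 120.0,
            "shift_rate_hz": 1.0,
            "vor_gain": 0.9,
            "head_drift_sd_dps": 5.0,
            "measurement_noise_sd_deg": 0.05,
            "n_calibration_points": 12,
            "true_gain_h_deg_per_px": 0.40,
            "true_gain_v_deg_per_px": 0.35,
            "true_offset_h_deg": -2.0,
            "true_offset_v_deg": 1.5,
            "locomotion_duration_s": 60.0,
            "locomotion_rate_hz": 120.0,
        },
        "pupil": {
            "mode": "threshold",  # "threshold" | "segmenter"
            "threshold": 60.0,
            "opening_radius": 2,
            "min_area_px2": 30.0,
            "train_epochs": 10,
            "train_samples": 250,
        },
        "gaze": {
            "max_gap_s": 0.05,
            "v_threshold_dps": 200.0,
            "min_shift_duration_s": 0.02,
            "min_fixation_duration_s": 0.05,
            "smoothing_window": 3,
        },
        "calibrate": {"error_bound_deg": 3.5},
        "analyze": {"apen_m": 2, "apen_r": 0.2, "apen_on": "position"},
    }


_SCHEMA_TYPES = {
    "seed": int,
    "simulate": dict,
    "pupil": dict,
    "gaze": dict,
    "calibrate": dict,
    "analyze": dict,
}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, reporting every invalid field."""
    defaults = default_config()
    errors = []
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    for key, value in config.items():
        if key == "out_dir":
            continue
        if key not in defaults:
            errors.append(f"unknown section or field: {key}")
            continue
        expected = _SCHEMA_TYPES[key]
        if not isinstance(value, expected):
            errors.append(f"{key}: expected {expected.__name__}, got {type(value).__name__}")
            continue
        if isinstance(value, dict):
            for sub, sval in value.items():
                if sub not in defaults[key]:
                    errors.append(f"{key}.{sub}: unknown field")
                elif sval is None:
                    errors.append(f"{key}.{sub}: missing value")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    merged = copy.deepcopy(defaults)
    for key, value in config.items():
        if key == "out_dir":
            merged[key] = value
        elif isinstance(value, dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def read_config(path) -> dict:
    """Read and validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def config_digest(config: dict) -> str:
    """Stable digest of a configuration (order-independent)."""
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, out_dir) -> dict:
    """Run simulate → pupil → calibrate → align → segment → analyze.

    Returns the run manifest (also written to ``manifest.json``): the config
    digest, per-stage outputs, and per-stage sample/warning counts.  A stage
    failure aborts with the stage name attached.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config_digest(cfg)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    manifest: dict = {"config_digest": digest, "stages": {}}
    seed = int(cfg["seed"])

    def stage(name):
        logger.info("pipeline stage: %s", name)
        manifest["stages"][name] = {"outputs": [], "counts": {}, "warnings": 0}
        return manifest["stages"][name]

    try:
        # --- simulate ---------------------------------------------------
        st = stage("simulate")
        sim = cfg["simulate"]
        spec = synthdata.TrajectorySpec(
            duration=sim["duration_s"],
            eye_rate=sim["eye_rate_hz"],
            head_rate=sim["head_rate_hz"],
            shift_rate=sim["shift_rate_hz"],
            vor_gain=sim["vor_gain"],
            head_drift_sd=sim["head_drift_sd_dps"],
            measurement_noise_sd=sim["measurement_noise_sd_deg"],
            seed=seed,
        )
        eye_df, head_df, truth = synthdata.gen_gaze_trajectory(spec)
        st["outputs"].append(str(write_table(eye_df, out / "eye_series.csv", "eye_series")))
        st["outputs"].append(str(write_table(head_df, out / "head_series.csv", "head_series")))
        st["counts"]["eye_samples"] = len(eye_df)
        st["counts"]["head_samples"] = len(head_df)
        st["counts"]["true_shifts"] = len(truth.shift_intervals)

        track, loco_truth = synthdata.gen_locomotion_track(
            duration=sim["locomotion_duration_s"],
            rate=sim["locomotion_rate_hz"],
            bouts=[(10.0, 20.0, 10.0), (30.0, 34.5, 8.0), (40.0, 42.0, 10.0)],
            head_height_cm=10.0,
            seed=seed + 1,
        )
        st["outputs"].append(str(write_table(track, out / "body_track.csv", "body_track")))
        st["counts"]["true_locomotion_bouts"] = len(loco_truth)

        # --- pupil + calibrate -------------------------------------------
        st = stage("pupil")
        pcfg = cfg["pupil"]
        rng = np.random.default_rng(seed + 2)
        n_cal = int(sim["n_calibration_points"])
        true_model = calibrate.CalibrationModel(
            gain_h=sim["true_gain_h_deg_per_px"],
            gain_v=sim["true_gain_v_deg_per_px"],
            offset_h=sim["true_offset_h_deg"],
            offset_v=sim["true_offset_v_deg"],
        )
        targets = np.column_stack(
            [rng.uniform(-8, 8, n_cal), rng.uniform(-6, 6, n_cal)]
        )
        # invert the true affine to place the pupil in each calibration frame
        px_h = (targets[:, 0] - true_model.offset_h) / true_model.gain_h
        px_v = (targets[:, 1] - true_model.offset_v) / true_model.gain_v
        frames, masks = [], []
        for ph, pv in zip(px_h, px_v):
            espec = synthdata.EyeImageSpec(
                pupil_center=(48.0 + pv, 48.0 + ph), pupil_axes=(11.0, 9.0)
            )
            img, msk = synthdata.gen_eye_image(espec)
            frames.append(img)
            masks.append(msk)
        write_frames(np.stack(frames), np.arange(n_cal) / 10.0, out / "calibration_frames")
        st["outputs"].append(str(out / "calibration_frames"))

        if pcfg["mode"] == "segmenter":
            imgs, msks, _ = synthdata.gen_eye_image_batch(int(pcfg["train_samples"]), seed=seed + 3)
            model = pupil.train_segmenter(imgs, msks, epochs=int(pcfg["train_epochs"]), seed=seed + 4)
            seg_masks = [pupil.segment_pupil(model, f)[1] for f in frames]
            pupil.save_model(model, out / "segmenter.npz")
            st["outputs"].append(str(out / "segmenter.npz"))
        else:
            seg_masks = [
                pupil.threshold_pupil(f, pcfg["threshold"], int(pcfg["opening_radius"]))
                for f in frames
            ]
        estimates = [pupil.fit_pupil_center(m, pcfg["min_area_px2"]) for m in seg_masks]
        est_df = pd.DataFrame(
            {
                "t_s": np.arange(n_cal) / 10.0,
                "center_row_px": [e.center[0] for e in estimates],
                "center_col_px": [e.center[1] for e in estimates],
                "valid": [int(e.valid) for e in estimates],
                "quality": [e.quality for e in estimates],
            }
        )
        st["outputs"].append(str(write_table(est_df, out / "pupil_estimates.csv", "pupil_estimates")))
        st["counts"]["frames"] = n_cal
        st["counts"]["valid_estimates"] = int(est_df["valid"].sum())

        st = stage("calibrate")
        ok = est_df["valid"].to_numpy(bool)
        pupil_px = np.column_stack(
            [est_df["center_col_px"].to_numpy(float) - 48.0, est_df["center_row_px"].to_numpy(float) - 48.0]
        )[ok]
        cal_model = calibrate.fit_calibration(pupil_px, targets[ok])
        cal_json = {
            "gain_h": cal_model.gain_h,
            "gain_v": cal_model.gain_v,
            "offset_h": cal_model.offset_h,
            "offset_v": cal_model.offset_v,
            "fit_residual_rms_deg": cal_model.fit_residual_rms,
            "n_points": cal_model.n_points,
            "config_digest": digest,
        }
        (out / "calibration.json").write_text(json.dumps(cal_json, indent=2))
        st["outputs"].append(str(out / "calibration.json"))
        st["counts"]["n_points"] = cal_model.n_points

        # error estimation against a scheduled synthetic scene
        square = synthdata.gen_scene_shapes(
            "polygon", vertices=[(-5, -5), (5, -5), (5, 5), (-5, 5)]
        )
        point = synthdata.gen_scene_shapes("point", position=(0.0, 0.0))
        scene = synthdata.schedule_scene([square, point])
        t_err = np.arange(0.0, 12.0, 1.0 / 30.0)
        gaze_on_scene = _gaze_on_scene(t_err, scene, rng, noise_sd=0.3)
        err_samples, err_summary = calibrate.estimate_error(
            t_err, gaze_on_scene, scene, bound=cfg["calibrate"]["error_bound_deg"]
        )
        write_table(err_samples, out / "gaze_error.csv")
        (out / "gaze_error_summary.json").write_text(
            json.dumps({**err_summary, "config_digest": digest}, indent=2)
        )
        st["outputs"] += [str(out / "gaze_error.csv"), str(out / "gaze_error_summary.json")]
        st["counts"]["registered_samples"] = err_summary["n_registered"]

        # --- align + segment ---------------------------------------------
        st = stage("gaze")
        gcfg = cfg["gaze"]
        series = gaze.align_streams(eye_df, head_df, max_gap=gcfg["max_gap_s"])
        st["outputs"].append(str(write_table(series.to_frame(), out / "gaze_series.csv", "gaze_series")))
        events = gaze.segment_gaze(
            series,
            v_threshold=gcfg["v_threshold_dps"],
            min_shift_duration=gcfg["min_shift_duration_s"],
            min_fixation_duration=gcfg["min_fixation_duration_s"],
            smoothing_window=int(gcfg["smoothing_window"]),
        )
        events_df = gaze.events_to_frame(events)
        st["outputs"].append(str(write_table(events_df, out / "gaze_events.csv", "events")))
        st["counts"]["samples"] = len(series)
        st["counts"]["shifts"] = sum(ev.label == "gaze_shift" for ev in events)
        st["counts"]["fixations"] = sum(ev.label == "gaze_fixation" for ev in events)

        # --- analyze -----------------------------------------------------
        st = stage("analyze")
        acfg = cfg["analyze"]
        table, binned, fit = kinematics.main_sequence(events)
        if len(table):
            write_table(table, out / "main_sequence.csv")
            st["outputs"].append(str(out / "main_sequence.csv"))
        behavior = kinematics.classify_locomotion(
            track[["x_cm", "y_cm"]].to_numpy(),
            track["head_z_cm"].to_numpy(),
            rate=sim["locomotion_rate_hz"],
        )
        report = kinematics.stability_report(
            series,
            events,
            apen_m=int(acfg["apen_m"]),
            apen_r=float(acfg["apen_r"]),
            apen_on=acfg["apen_on"],
        )
        report["main_sequence_fit"] = fit
        report["true_vor_gain"] = truth.true_vor_gain
        report["locomotion"] = {
            "epochs": [[ep.label, ep.t_start, ep.t_end] for ep in behavior],
            "true_intervals": loco_truth,
        }
        report["config_digest"] = digest
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        st["outputs"].append(str(out / "report.json"))
        st["counts"]["main_sequence_rows"] = int(len(table))
    except Exception as exc:
        failed = next(reversed(manifest["stages"]))
        raise RuntimeError(f"pipeline stage '{failed}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _gaze_on_scene(t, scene, rng, noise_sd=0.3):
    """Synthetic gaze that tracks whichever primitive is active, plus noise."""
    g = np.zeros((t.size, 2))
    for prim in scene:
        t_on, t_off = prim.active_interval if prim.active_interval else (t[0], t[-1])
        m = (t > t_on) & (t < t_off)
        if not m.any():
            continue
        if prim.kind == "point":
            g[m] = prim.coords[0]
        else:
            frac = rng.uniform(0, 1, int(m.sum()))
            g[m] = prim.coords[0] + frac[:, None] * (prim.coords[1] - prim.coords[0])
    return g + rng.normal(0, noise_sd, g.shape)
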