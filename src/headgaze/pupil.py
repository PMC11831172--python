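"""Pupil detection: thresholding baseline, trainable segmenter, ellipse fit.

Plain intensity thresholding finds the pupil only under even illumination;
shadows and gradients put off-pupil pixels below any fixed cutoff.  The
trainable segmenter classifies each pixel from a multi-scale feature vector
(intensity, Gaussian pyramid, difference-of-Gaussian band-pass channels,
local contrast and image-plane position) with a small fully connected
network trained by seeded mini-batch Adam on binary cross-entropy.  It is
implemented in plain numpy so that training is deterministic, CPU-cheap and
dependency-free; because the network is pixel-wise it applies to any frame
size.  The mask-to-center reduction keeps the largest connected component
and fits an ellipse to its boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "EyeFrame",
    "PupilEstimate",
    "SegmenterModel",
    "threshold_pupil",
    "pupil_features",
    "train_segmenter",
    "segment_pupil",
    "fit_pupil_center",
    "save_model",
    "load_model",
]

DEFAULT_CONFIG = {
    "hidden_sizes": (48, 24),
    "learning_rate": 3e-3,
    "batch_size": 512,
    "binarize_cutoff": 0.5,
    "opening_radius": 2,
    "min_area": 30.0,
    "bg_per_fg": 2.0,  # background pixels sampled per pupil pixel
    "strict_input_size": False,
}

FEATURE_VERSION = 1


@dataclass(frozen=True)
class EyeFrame:
    """One timestamped grayscale eye-camera frame (gray levels 0–255)."""

    t: float
    image: np.ndarray

    def __post_init__(self):
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2 or img.size == 0:
            raise ValueError("EyeFrame.image must be a nonempty 2-D array")
        if not math.isfinite(self.t):
            raise ValueError("EyeFrame.t must be finite")
        object.__setattr__(self, "image", img)


@dataclass(frozen=True)
class PupilEstimate:
    """Ellipse-fit pupil location for one frame.

    ``center`` is (row, col) in pixels; ``axes`` is (semi-major, semi-minor);
    ``quality`` is the ratio of mask-component area to fitted-ellipse area,
    clipped to [0, 1] (1 = the component is exactly ellipse-shaped).
    """

    t: float = float("nan")
    center: tuple[float, float] = (float("nan"), float("nan"))
    axes: tuple[float, float] = (float("nan"), float("nan"))
    angle: float = float("nan")
    area: float = 0.0
    valid: bool = False
    quality: float = 0.0


# ---------------------------------------------------------------------------
# Thresholding baseline
# ---------------------------------------------------------------------------

def threshold_pupil(frame, threshold: float, opening_radius: int = 2) -> np.ndarray:
    """Baseline dark-pixel detector: ``image < threshold`` + one opening.

    The morphological opening (disk of ``opening_radius`` pixels) removes
    speckle but cannot remove extended dark regions such as corner shadows —
    the documented failure mode of this approach.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    image = frame.image if isinstance(frame, EyeFrame) else np.asarray(frame, dtype=float)
    mask = image < threshold
    if opening_radius > 0:
        mask = morphology.opening(mask, morphology.disk(opening_radius))
    return mask


# ---------------------------------------------------------------------------
# Pixel features
# ---------------------------------------------------------------------------

def pupil_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack (h, w, n_features), float32.

    Channels: normalized intensity; Gaussian pyramid (sigma 1, 2, 4, 8, 16);
    difference-of-Gaussian band-pass channels (pupil-scale blob detectors);
    high-pass intensity (intensity minus large-scale illumination, the
    channel that cancels smooth gradients); local standard deviation;
    gradient magnitude; normalized row/column position (corner shadows live
    at the image rim, the pupil near the center of the eye camera's view).
    """
    x = np.asarray(image, dtype=np.float64) / 255.0
    g = [ndimage.gaussian_filter(x, s) for s in (1, 2, 4, 8, 16)]
    local_var = np.maximum(ndimage.gaussian_filter(x * x, 2) - g[1] ** 2, 0.0)
    gy, gx = np.gradient(g[0])
    h, w = x.shape
    rows = (np.arange(h, dtype=np.float64)[:, None] / max(h - 1, 1) * 2 - 1) * np.ones((1, w))
    cols = (np.arange(w, dtype=np.float64)[None, :] / max(w - 1, 1) * 2 - 1) * np.ones((h, 1))
    feats = [
        x,
        g[0],
        g[1],
        g[2],
        g[3],
        g[0] - g[1],
        g[1] - g[2],
        g[2] - g[3],
        g[3] - g[4],
        x - g[4],  # high-pass: gradient-immune intensity
        np.sqrt(local_var),
        np.hypot(gx, gy),
        rows,
        cols,
        np.minimum(1.0 - np.abs(rows), 1.0 - np.abs(cols)),  # distance to image rim
    ]
    return np.stack(feats, axis=-1).astype(np.float32)


N_FEATURES = 15


# ---------------------------------------------------------------------------
# The segmentation network (numpy MLP over pixel features)
# ---------------------------------------------------------------------------

@dataclass
class SegmenterModel:
    """Pixel-wise segmentation network: weights, config and training record."""

    weights: list  # [(W, b), ...] per layer
    input_size: tuple[int, int]
    config: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG))
    training_meta: dict = field(default_factory=dict)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Probability of pupil for each feature row (n, F) -> (n,)."""
        a = X
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(self.weights):
            z = a @ W + b
            a = np.maximum(z, 0.0) if i < n_layers - 1 else z
        return 1.0 / (1.0 + np.exp(-a[:, 0]))


def _init_weights(sizes: list[int], rng: np.random.Generator) -> list:
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        weights.append((W, np.zeros(fan_out)))
    return weights


def _forward_cached(weights, X):
    acts = [X]
    n_layers = len(weights)
    for i, (W, b) in enumerate(weights):
        z = acts[-1] @ W + b
        acts.append(np.maximum(z, 0.0) if i < n_layers - 1 else z)
    p = 1.0 / (1.0 + np.exp(-acts[-1][:, 0]))
    return acts, p


def _backward(weights, acts, p, y):
    grads = []
    n = y.size
    delta = ((p - y) / n)[:, None]  # d(BCE)/d(logit)
    for i in range(len(weights) - 1, -1, -1):
        W, _ = weights[i]
        a_prev = acts[i]
        gW = a_prev.T @ delta
        gb = delta.sum(axis=0)
        grads.append((gW, gb))
        if i > 0:
            delta = (delta @ W.T) * (acts[i] > 0)
    grads.reverse()
    return grads


def _sample_training_pixels(images, masks, rng, bg_per_fg):
    """Balanced per-image pixel sampling: all pupil pixels + background.

    Half the background sample is drawn from the darkest background pixels
    (hard negatives: shadows and gradient-darkened corners look like pupil
    to a purely intensity-driven classifier), half uniformly.
    """
    X_parts, y_parts = [], []
    for img, msk in zip(images, masks):
        feats = pupil_features(img).reshape(-1, N_FEATURES)
        flat = msk.reshape(-1).astype(bool)
        fg_idx = np.flatnonzero(flat)
        bg_idx = np.flatnonzero(~flat)
        n_bg = min(int(round(bg_per_fg * fg_idx.size)), bg_idx.size)
        n_hard = n_bg // 2
        dark_order = bg_idx[np.argsort(img.reshape(-1)[bg_idx], kind="stable")]
        hard_sel = dark_order[:n_hard]
        rest = np.setdiff1d(bg_idx, hard_sel, assume_unique=True)
        rand_sel = rng.choice(rest, size=min(n_bg - n_hard, rest.size), replace=False)
        idx = np.concatenate([fg_idx, hard_sel, rand_sel])
        X_parts.append(feats[idx])
        y_parts.append(flat[idx].astype(np.float64))
    return np.concatenate(X_parts), np.concatenate(y_parts)


def train_segmenter(
    images,
    masks,
    epochs: int = 10,
    seed: int = 0,
    config: dict | None = None,
) -> SegmenterModel:
    """Train the pixel-wise segmenter on (image, mask) pairs.

    All images must share one size; masks must be binary.  Identical
    (data, epochs, seed, config) reproduce bit-identical weights.  The
    recorded ``loss_trace`` holds the mean training binary cross-entropy
    per epoch.  ``epochs=0`` returns the freshly initialized (untrained)
    network with an empty loss trace.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    images = [np.asarray(im, dtype=float) for im in images]
    masks = [np.asarray(m) for m in masks]
    if not images:
        raise ValueError("training set is empty")
    if len(images) != len(masks):
        raise ValueError("images and masks differ in length")
    shape0 = images[0].shape
    for i, (im, m) in enumerate(zip(images, masks)):
        if im.shape != shape0 or m.shape != shape0:
            raise ValueError(f"sample {i}: image/mask shape {im.shape}/{m.shape} != {shape0}")
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1, 255, True, False))):
            raise ValueError(f"sample {i}: mask is not binary")
    masks = [m.astype(bool) for m in masks]

    rng = np.random.default_rng(seed)
    sizes = [N_FEATURES, *cfg["hidden_sizes"], 1]
    weights = _init_weights(sizes, rng)
    meta = {
        "epochs": int(epochs),
        "n_samples": len(images),
        "seed": int(seed),
        "loss_trace": [],
        "feature_version": FEATURE_VERSION,
    }
    model = SegmenterModel(weights=weights, input_size=tuple(shape0), config=cfg, training_meta=meta)
    if epochs == 0:
        return model

    X, y = _sample_training_pixels(images, masks, rng, cfg["bg_per_fg"])
    lr, batch = cfg["learning_rate"], int(cfg["batch_size"])
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    m_state = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    v_state = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    step = 0
    for _ in range(int(epochs)):
        order = rng.permutation(X.shape[0])
        losses = []
        for start in range(0, X.shape[0], batch):
            sel = order[start : start + batch]
            acts, p = _forward_cached(weights, X[sel])
            yb = y[sel]
            p_c = np.clip(p, 1e-12, 1 - 1e-12)
            losses.append(float(-np.mean(yb * np.log(p_c) + (1 - yb) * np.log(1 - p_c))))
            grads = _backward(weights, acts, p, yb)
            step += 1
            corr1 = 1 - beta1**step
            corr2 = 1 - beta2**step
            for i, ((W, b), (gW, gb)) in enumerate(zip(weights, grads)):
                mW, mb = m_state[i]
                vW, vb = v_state[i]
                mW = beta1 * mW + (1 - beta1) * gW
                mb = beta1 * mb + (1 - beta1) * gb
                vW = beta2 * vW + (1 - beta2) * gW**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                m_state[i] = (mW, mb)
                v_state[i] = (vW, vb)
                W -= lr * (mW / corr1) / (np.sqrt(vW / corr2) + eps_adam)
                b -= lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps_adam)
        meta["loss_trace"].append(float(np.mean(losses)))
    return model


def segment_pupil(model: SegmenterModel, frame) -> tuple[np.ndarray, np.ndarray]:
    """Apply the segmenter to one frame: (probability map, binary mask).

    The network is pixel-wise, so any frame size is accepted unless the
    model was configured with ``strict_input_size``.
    """
    image = frame.image if isinstance(frame, EyeFrame) else np.asarray(frame, dtype=float)
    if model.config.get("strict_input_size") and image.shape != tuple(model.input_size):
        raise ValueError(
            f"frame size {image.shape} incompatible with model input size "
            f"{tuple(model.input_size)} and resizing is disabled"
        )
    feats = pupil_features(image).reshape(-1, N_FEATURES)
    prob = model.forward(feats).reshape(image.shape)
    mask = prob >= model.config.get("binarize_cutoff", 0.5)
    return prob, mask


# ---------------------------------------------------------------------------
# Mask -> PupilEstimate
# ---------------------------------------------------------------------------

def fit_pupil_center(mask: np.ndarray, min_area: float = 30.0, t: float = float("nan")) -> PupilEstimate:
    """Reduce a binary mask to an ellipse-fit pupil estimate.

    Keeps the largest connected component; if its area is below ``min_area``
    the estimate is returned with ``valid=False``.  An ellipse is fitted by
    least squares to the component boundary, falling back to image moments
    when the conic fit is degenerate.  Invalidity is a value, never an
    exception.
    """
    mask = np.asarray(mask).astype(bool)
    labels = measure.label(mask)
    if labels.max() == 0:
        return PupilEstimate(t=t)
    regions = measure.regionprops(labels)
    region = max(regions, key=lambda r: r.area)
    if region.area < min_area:
        return PupilEstimate(t=t, area=float(region.area))

    component = labels == region.label
    contours = measure.find_contours(component.astype(float), 0.5)
    params = None
    if contours:
        boundary = max(contours, key=len)
        if len(boundary) >= 5:
            ellipse = measure.EllipseModel.from_estimate(boundary)
            if ellipse:
                (rc, cc), (a, b), theta = ellipse.center, ellipse.axis_lengths, ellipse.theta
                if np.isfinite([rc, cc, a, b, theta]).all() and a > 0 and b > 0:
                    params = (rc, cc, a, b, theta)
    if params is None:
        # moment-based fallback
        rc, cc = region.centroid
        a = region.axis_major_length / 2.0 or 1.0
        b = region.axis_minor_length / 2.0 or a
        theta = region.orientation
        params = (rc, cc, a, b, theta)
    rc, cc, a, b, theta = params
    if b > a:
        a, b = b, a
        theta += math.pi / 2
    quality = float(np.clip(region.area / (math.pi * a * b), 0.0, 1.0))
    h, w = mask.shape
    valid = 0 <= rc < h and 0 <= cc < w and region.area >= min_area
    return PupilEstimate(
        t=t,
        center=(float(rc), float(cc)),
        axes=(float(a), float(b)),
        angle=float(theta % math.pi),
        area=float(region.area),
        valid=bool(valid),
        quality=quality,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: SegmenterModel, path) -> None:
    """Serialize a model to a single ``.npz`` file (weights + JSON metadata)."""
    arrays = {}
    for i, (W, b) in enumerate(model.weights):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    header = {
        "n_layers": len(model.weights),
        "input_size": list(model.input_size),
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in model.config.items()},
        "training_meta": model.training_meta,
    }
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_model(path) -> SegmenterModel:
    """Load a model saved by :func:`save_model`; outputs are bit-identical."""
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["header"]).decode())
        weights = [
            (data[f"W{i}"].copy(), data[f"b{i}"].copy()) for i in range(header["n_layers"])
        ]
    cfg = header["config"]
    if "hidden_sizes" in cfg:
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
    return SegmenterModel(
        weights=weights,
        input_size=tuple(header["input_size"]),
        config=cfg,
        training_meta=header["training_meta"],
    )
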