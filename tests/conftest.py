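import numpy as np
import pytest

from headgaze import pupil, synthdata

# the printed training setup: ~250 samples, 10 epochs
TRAIN_N, TRAIN_EPOCHS = 250, 10
TRAIN_DATA_SEED, TRAIN_SEED, TEST_DATA_SEED = 10, 0, 99


@pytest.fixture(scope="session")
def trained_segmenter():
    """Segmenter trained once per session on the randomized synthetic family."""
    images, masks, _ = synthdata.gen_eye_image_batch(TRAIN_N, seed=TRAIN_DATA_SEED)
    return pupil.train_segmenter(images, masks, epochs=TRAIN_EPOCHS, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def heldout_eye_images():
    """Fresh (never trained on) images with ground truth, noiseless family."""
    return synthdata.gen_eye_image_batch(50, seed=TEST_DATA_SEED)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0


def match_shifts(detected_events, truth):
    """Greedy overlap matching of detected gaze shifts against truth intervals.

    Returns (n_matched, n_true, n_detected, relative amplitude errors).
    """
    shifts = [ev for ev in detected_events if ev.label == "gaze_shift"]
    used = set()
    amp_err = []
    matched = 0
    for (t0, t1), amp in zip(truth.shift_intervals, truth.amp_gaze):
        for i, ev in enumerate(shifts):
            if i in used:
                continue
            if ev.t_start < t1 and ev.t_end > t0:
                matched += 1
                used.add(i)
                amp_err.append(abs(ev.channels["gaze_h"].amplitude - amp) / abs(amp))
                break
    return matched, len(truth.shift_intervals), len(shifts), np.asarray(amp_err)
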