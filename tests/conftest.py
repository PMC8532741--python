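import numpy as np
import pandas as pd
import pytest

from hscore.features import Path
from hscore.trajectory_io import (DETECTIONS_COLUMNS, RoomCalibration,
                                  Trajectory)


@pytest.fixture
def calibration():
    return RoomCalibration(room_width_cm=340.0, room_height_cm=220.0,
                           image_width_px=1280.0, image_height_px=720.0,
                           fps=30.0)


@pytest.fixture
def random_path_factory():
    """Smooth-ish random walks in room coordinates, reproducible per seed."""
    def make(seed, n=80, scale=8.0):
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, scale, (n - 1, 2))
        pts = np.vstack([[150.0, 100.0], np.cumsum(steps, axis=0) + [150.0, 100.0]])
        return Path(points=pts, times_s=np.arange(n) / 30.0)
    return make


def make_trajectory(x, y, conf=None, fps=30.0, presence=None, mean_conf=None,
                    object_class="dog"):
    """Build a Trajectory directly; NaN in x marks missing slots."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    conf = np.where(np.isnan(x), np.nan,
                    0.9 if conf is None else np.asarray(conf, dtype=float))
    detected = ~np.isnan(x)
    return Trajectory(
        times_s=np.arange(len(x)) / fps, x_cm=x, y_cm=y, confidences=conf,
        object_class=object_class,
        presence_fraction=detected.mean() if presence is None else presence,
        mean_confidence=(float(np.nanmean(conf)) if mean_conf is None
                         else mean_conf),
        fps=fps,
    )


def detections_df(rows):
    """Detections table from (frame, time, object, x, y, conf) tuples."""
    df = pd.DataFrame(rows, columns=["frame", "time_s", "object",
                                     "x_px", "y_px", "confidence"])
    for col in ("x_min", "y_min", "x_max", "y_max"):
        df[col] = ""
    return df[list(DETECTIONS_COLUMNS)]
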