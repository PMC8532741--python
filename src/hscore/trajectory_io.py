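"""Read, calibrate, clean and quality-filter per-frame tracking records.

A tracking system exports one CSV row per detection: frame index, time
stamp, object class (``dog`` or ``robot``), an image-plane point, an
optional bounding box and a detection confidence.  This module converts
such files into analysis-ready :class:`Trajectory` objects in room (cm)
coordinates, provides the two clean-up operations the tracking pipeline
applies (moving-average smoothing and short-gap interpolation) and the
video inclusion rule used for clinical recordings: at least 70% of frames
with the animal detected and mean detection certainty of at least 70%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path as FilePath

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RoomCalibration",
    "Trajectory",
    "QualityResult",
    "read_detections",
    "write_detections",
    "smooth",
    "fill_gaps",
    "quality_filter",
    "DETECTIONS_COLUMNS",
]

#: Column order of the detections CSV dialect.
DETECTIONS_COLUMNS = (
    "frame", "time_s", "object", "x_px", "y_px",
    "x_min", "y_min", "x_max", "y_max", "confidence",
)

_OBJECT_CLASSES = ("dog", "robot")


@dataclass(frozen=True)
class RoomCalibration:
    """Mapping between image pixels and consultation-room centimetres.

    Scaling is anisotropic (separate x and y factors) because the room and
    the image generally have different aspect ratios.  The image origin is
    the top-left corner, x to the right, y downward.
    """

    room_width_cm: float
    room_height_cm: float
    image_width_px: float
    image_height_px: float
    fps: float

    def __post_init__(self) -> None:
        for name in ("room_width_cm", "room_height_cm", "image_width_px",
                     "image_height_px", "fps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def scale_x(self) -> float:
        """cm per pixel along x."""
        return self.room_width_cm / self.image_width_px

    @property
    def scale_y(self) -> float:
        """cm per pixel along y."""
        return self.room_height_cm / self.image_height_px

    def px_to_cm(self, x_px, y_px):
        return np.asarray(x_px) * self.scale_x, np.asarray(y_px) * self.scale_y

    def cm_to_px(self, x_cm, y_cm):
        return np.asarray(x_cm) / self.scale_x, np.asarray(y_cm) / self.scale_y

    @classmethod
    def from_file(cls, path) -> "RoomCalibration":
        """Load from a YAML or JSON config with the five canonical keys."""
        text = FilePath(path).read_text(encoding="utf-8")
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        keys = ("room_width_cm", "room_height_cm", "image_width_px",
                "image_height_px", "fps")
        missing = [k for k in keys if k not in data]
        if missing:
            raise ValueError(f"calibration config missing keys: {missing}")
        return cls(**{k: float(data[k]) for k in keys})


@dataclass
class Trajectory:
    """One object's positions over the full trial span, one slot per frame.

    Missing detections are NaN slots.  ``presence_fraction`` and
    ``mean_confidence`` describe the *raw* detections and are preserved by
    the clean-up operations, so the quality criterion is always evaluated
    against what the tracker actually saw.
    """

    times_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    confidences: np.ndarray
    object_class: str
    presence_fraction: float
    mean_confidence: float
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        self.confidences = np.asarray(self.confidences, dtype=float)
        n = len(self.times_s)
        if not (len(self.x_cm) == len(self.y_cm) == len(self.confidences) == n):
            raise ValueError("times_s, x_cm, y_cm, confidences must share length")
        if not 0.0 <= self.presence_fraction <= 1.0:
            raise ValueError("presence_fraction must lie in [0, 1]")
        if self.object_class not in _OBJECT_CLASSES:
            raise ValueError(f"object_class must be one of {_OBJECT_CLASSES}")

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    @property
    def detected(self) -> np.ndarray:
        """Boolean mask of slots holding a position (original or filled)."""
        return ~np.isnan(self.x_cm)


@dataclass(frozen=True)
class QualityResult:
    """Outcome of the inclusion rule, with every violated criterion listed."""

    passed: bool
    reasons: tuple = ()
    presence_fraction: float = float("nan")
    mean_confidence: float = float("nan")


def _position_from_row(df: pd.DataFrame):
    """Detection position: bbox centroid when the box is present, else the point."""
    has_bbox = df[["x_min", "y_min", "x_max", "y_max"]].notna().all(axis=1)
    x = np.where(has_bbox, (df["x_min"] + df["x_max"]) / 2.0, df["x_px"])
    y = np.where(has_bbox, (df["y_min"] + df["y_max"]) / 2.0, df["y_px"])
    return x.astype(float), y.astype(float)


def read_detections(path, calibration: RoomCalibration) -> dict:
    """Parse a detections CSV into one calibrated :class:`Trajectory` per object.

    The trial span is ``[min frame, max frame]`` over the whole file; frames
    without a row for an object become missing slots.  Positions outside the
    calibrated room are clipped with a warning.

    Raises
    ------
    ValueError
        on an empty file, a malformed row (reported with its line number),
        or duplicate (frame, object) rows.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != list(DETECTIONS_COLUMNS):
        raise ValueError(
            f"unexpected header {list(raw.columns)}; expected {list(DETECTIONS_COLUMNS)}")
    if len(raw) == 0:
        raise ValueError(f"empty detections file: {path}")

    df = raw.copy()
    numeric = ["frame", "time_s", "x_px", "y_px", "x_min", "y_min",
               "x_max", "y_max", "confidence"]
    for col in numeric:
        vals = raw[col].mask(raw[col] == "")
        converted = pd.to_numeric(vals, errors="coerce")
        bad = converted.isna() & vals.notna()
        if bad.any():
            # +2: 1-based line numbering plus the header line
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}: malformed value {raw[col][bad.idxmax()]!r} "
                             f"in column {col!r} at line {line}")
        df[col] = converted
    required = df[["frame", "time_s", "x_px", "y_px", "confidence"]].isna().any(axis=1)
    if required.any():
        line = int(required.idxmax()) + 2
        raise ValueError(f"{path}: missing required value at line {line}")

    bad_obj = ~df["object"].isin(_OBJECT_CLASSES)
    if bad_obj.any():
        line = int(bad_obj.idxmax()) + 2
        raise ValueError(f"{path}: unknown object class at line {line}")
    if df.duplicated(subset=["frame", "object"]).any():
        dup = df[df.duplicated(subset=["frame", "object"])].iloc[0]
        raise ValueError(f"{path}: duplicate row for frame {int(dup['frame'])}, "
                         f"object {dup['object']!r}")
    if (df["confidence"].lt(0) | df["confidence"].gt(1)).any():
        raise ValueError(f"{path}: confidence outside [0, 1]")

    df["frame"] = df["frame"].astype(int)
    first, last = int(df["frame"].min()), int(df["frame"].max())
    span = last - first + 1
    frames = np.arange(first, last + 1)
    times = frames / calibration.fps

    out: dict[str, Trajectory] = {}
    for obj, sub in df.groupby("object"):
        sub = sub.sort_values("frame")
        if not np.all(np.diff(sub["time_s"].to_numpy()) > 0):
            raise ValueError(f"{path}: time_s not strictly increasing for {obj!r}")
        x_px, y_px = _position_from_row(sub)
        x_cm, y_cm = calibration.px_to_cm(x_px, y_px)
        xs = np.full(span, np.nan)
        ys = np.full(span, np.nan)
        cs = np.full(span, np.nan)
        idx = sub["frame"].to_numpy() - first
        xs[idx], ys[idx], cs[idx] = x_cm, y_cm, sub["confidence"].to_numpy()

        tol = 1e-6  # float round-trip slack at the exact room boundary
        oob = ((xs < -tol) | (xs > calibration.room_width_cm + tol)
               | (ys < -tol) | (ys > calibration.room_height_cm + tol))
        if np.nansum(oob) > 0:
            warnings.warn(f"{path}: {int(np.nansum(oob))} {obj} positions outside "
                          "the calibrated room were clipped", stacklevel=2)
        xs = np.clip(xs, 0.0, calibration.room_width_cm)
        ys = np.clip(ys, 0.0, calibration.room_height_cm)

        out[obj] = Trajectory(
            times_s=times, x_cm=xs, y_cm=ys, confidences=cs, object_class=obj,
            presence_fraction=len(sub) / span,
            mean_confidence=float(np.mean(sub["confidence"])),
            fps=calibration.fps,
        )
    return out


def write_detections(df: pd.DataFrame, path) -> None:
    """Write a detections table in the canonical CSV dialect."""
    missing = [c for c in DETECTIONS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detections table missing columns {missing}")
    df.loc[:, DETECTIONS_COLUMNS].to_csv(path, index=False)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrunken windows at the ends."""
    half = window // 2
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def smooth(traj: Trajectory, window: int = 5) -> Trajectory:
    """Moving-average smoothing over the sequence of detected positions.

    The window runs over detected samples (missing slots are skipped and
    stay missing), is centered, shrinks at the sequence ends, and
    ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return replace(traj)
    mask = traj.detected
    x, y = traj.x_cm.copy(), traj.y_cm.copy()
    if mask.sum() >= 2:
        x[mask] = _moving_average(traj.x_cm[mask], window)
        y[mask] = _moving_average(traj.y_cm[mask], window)
    return replace(traj, x_cm=x, y_cm=y)


def fill_gaps(traj: Trajectory, max_gap_frames: int = 15) -> Trajectory:
    """Linearly interpolate interior detection gaps of at most ``max_gap_frames``.

    Longer runs and leading/trailing gaps stay missing; interpolated slots
    get NaN confidence and ``presence_fraction`` is left at its raw value so
    gap filling never inflates the inclusion criterion.
    """
    if max_gap_frames < 1:
        raise ValueError("max_gap_frames must be >= 1")
    mask = traj.detected
    if mask.all() or mask.sum() < 2:
        return replace(traj)
    x, y = traj.x_cm.copy(), traj.y_cm.copy()
    det_idx = np.flatnonzero(mask)
    for a, b in zip(det_idx[:-1], det_idx[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap_frames:
            t = np.arange(1, gap + 1) / (gap + 1)
            x[a + 1:b] = traj.x_cm[a] + t * (traj.x_cm[b] - traj.x_cm[a])
            y[a + 1:b] = traj.y_cm[a] + t * (traj.y_cm[b] - traj.y_cm[a])
    return replace(traj, x_cm=x, y_cm=y)


def quality_filter(traj: Trajectory, min_presence: float = 0.70,
                   min_confidence: float = 0.70) -> QualityResult:
    """Video inclusion rule: enough frames detected, confident enough.

    Both thresholds are inclusive (``>=``).  Returns the decision plus every
    violated criterion, so rejected recordings can be reported with reasons.
    """
    if not (0 < min_presence <= 1 and 0 < min_confidence <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    reasons = []
    if traj.presence_fraction < min_presence:
        reasons.append(
            f"presence: {traj.presence_fraction:.3f} < {min_presence:.2f}")
    if not traj.mean_confidence >= min_confidence:
        reasons.append(
            f"confidence: {traj.mean_confidence:.3f} < {min_confidence:.2f}")
    return QualityResult(
        passed=not reasons, reasons=tuple(reasons),
        presence_fraction=traj.presence_fraction,
        mean_confidence=traj.mean_confidence,
    )
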