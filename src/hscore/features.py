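"""Per-trial movement features: locomotion, tortuosity and robot interaction.

The feature set mirrors what behavioral experts describe when watching a
hyperactive dog — fast, erratic, high-coverage movement — plus the five
tortuosity indices of the movement-ecology literature:

* straightness: net displacement over total path length, in [0, 1];
* mean squared displacement (MSD) over a set of time lags;
* intensity of use: path length over the square root of the used area
  (convex hull);
* sinuosity: ``S = 2 * [p * ((1+c)/(1-c) + b**2)]**(-1/2)`` computed on a
  constant-step rediscretized path, where ``p`` is the mean step length,
  ``c`` the mean cosine of turning angles and ``b`` the coefficient of
  variation of step length;
* fractal dimension D of the path by the divider (caliper) method.

Features that are undefined on a given path (degenerate hull, path too
short to rediscretize, ...) are reported as NaN with a reason rather than
raising, so a whole cohort can be featurized in one pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint

from .trajectory_io import Trajectory

__all__ = [
    "Path",
    "FeatureConfig",
    "FeatureVector",
    "SinuosityParams",
    "total_distance",
    "average_speed",
    "straightness",
    "mean_squared_displacement",
    "intensity_of_use",
    "rediscretize",
    "sinuosity_params",
    "sinuosity_from_params",
    "sinuosity",
    "fractal_d",
    "locomotion_extras",
    "robot_interaction_features",
    "extract_features",
    "E_FEATURE_IDS",
    "DR_FEATURE_IDS",
]


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    out = (-a + np.pi) % (2.0 * np.pi)
    return np.pi - out


@dataclass
class Path:
    """A gap-free polyline in room coordinates with per-step durations."""

    points: np.ndarray   # (n, 2) cm
    times_s: np.ndarray  # (n,) seconds

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) != len(self.times_s):
            raise ValueError("points and times_s must share length")
        if np.isnan(self.points).any():
            raise ValueError("Path does not admit missing positions")

    @classmethod
    def from_trajectory(cls, traj: Trajectory) -> "Path":
        mask = traj.detected
        pts = np.column_stack([traj.x_cm[mask], traj.y_cm[mask]])
        return cls(points=pts, times_s=traj.times_s[mask])

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def dt_s(self) -> np.ndarray:
        return np.diff(self.times_s)

    @property
    def step_lengths(self) -> np.ndarray:
        return np.hypot(*np.diff(self.points, axis=0).T)

    @property
    def headings(self) -> np.ndarray:
        d = np.diff(self.points, axis=0)
        return np.arctan2(d[:, 1], d[:, 0])

    @property
    def turning_angles(self) -> np.ndarray:
        """Signed heading change at each interior vertex, in (-pi, pi]."""
        return _wrap_angle(np.diff(self.headings))

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if self.n_points else 0.0


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable feature parameters (centimetres / seconds throughout)."""

    msd_lags_s: tuple = (1.0, 2.0, 5.0, 10.0, 30.0)
    sinuosity_q_cm: float = 5.0
    fractal_eps_cm: tuple = (2.0, 50.0)
    fractal_n_dividers: int = 10
    move_threshold_cms: float = 2.0
    grid_cell_cm: float = 20.0
    proximity_cm: float = 50.0
    min_points: int = 10


@dataclass
class FeatureVector:
    """Named scalar features for one trial, with reasons for missing ones."""

    values: dict
    trial_type: str = "E"
    dog_id: str = ""
    visit: str = "first"
    missing: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# expert-derived locomotion features


def total_distance(path: Path) -> float:
    """Total path length (cm); NaN on fewer than two points."""
    if path.n_points < 2:
        return float("nan")
    return float(path.step_lengths.sum())


def average_speed(path: Path) -> float:
    """Mean travel speed (cm/s) over the trial."""
    elapsed = path.duration_s
    if elapsed <= 0:
        raise ValueError("average_speed needs positive elapsed time")
    return total_distance(path) / elapsed


def locomotion_extras(path: Path, move_threshold: float = 2.0,
                      grid_cell: float = 20.0, room_cm=None) -> dict:
    """Simple per-trial movement statistics beyond distance and speed.

    Room coverage is measured on a square grid over the room (or over the
    path's bounding box when the room is unknown).
    """
    out = {}
    if path.n_points < 2:
        return {k: float("nan") for k in
                ("fraction_time_moving", "mean_abs_turn_rad", "turn_std_rad",
                 "n_reversals", "room_coverage", "speed_p90_cms")}
    dt = path.dt_s
    speeds = np.divide(path.step_lengths, dt, out=np.zeros_like(dt),
                       where=dt > 0)
    out["fraction_time_moving"] = float(dt[speeds > move_threshold].sum() / dt.sum())
    turns = path.turning_angles
    out["mean_abs_turn_rad"] = float(np.abs(turns).mean()) if len(turns) else float("nan")
    out["turn_std_rad"] = float(np.std(turns)) if len(turns) else float("nan")
    out["n_reversals"] = float((np.abs(turns) > np.pi / 2).sum()) if len(turns) else float("nan")
    out["speed_p90_cms"] = float(np.percentile(speeds, 90))

    if room_cm is not None:
        w, h = room_cm
        origin = np.array([0.0, 0.0])
    else:
        lo = path.points.min(axis=0)
        hi = path.points.max(axis=0)
        w, h = np.maximum(hi - lo, grid_cell)
        origin = lo
    ncols = max(1, math.ceil(w / grid_cell))
    nrows = max(1, math.ceil(h / grid_cell))
    cells = np.floor((path.points - origin) / grid_cell).astype(int)
    cells = np.clip(cells, [0, 0], [ncols - 1, nrows - 1])
    occupied = len(np.unique(cells[:, 0] * nrows + cells[:, 1]))
    out["room_coverage"] = occupied / (ncols * nrows)
    return out


# ---------------------------------------------------------------------------
# tortuosity indices


def straightness(path: Path) -> float:
    """Net displacement divided by total path length; 1 = perfectly straight."""
    L = total_distance(path)
    if not L > 0:
        return float("nan")
    net = float(np.hypot(*(path.points[-1] - path.points[0])))
    return net / L


def mean_squared_displacement(path: Path, lags_s) -> tuple:
    """MSD(tau) averaged over start times, per lag, plus the mean over lags.

    Sampling is assumed (near-)uniform: each lag is converted to a whole
    number of samples using the median sampling interval.  Lags with no
    admissible start time are omitted with a warning.
    """
    if path.n_points < 2:
        return {}, float("nan")
    dt = float(np.median(path.dt_s))
    curve = {}
    for tau in lags_s:
        m = int(round(tau / dt))
        if m < 1 or m > path.n_points - 1:
            warnings.warn(f"MSD lag {tau} s inadmissible for this path; omitted",
                          stacklevel=2)
            continue
        d = path.points[m:] - path.points[:-m]
        curve[float(tau)] = float(np.mean(np.einsum("ij,ij->i", d, d)))
    summary = float(np.mean(list(curve.values()))) if curve else float("nan")
    return curve, summary


def intensity_of_use(path: Path) -> float:
    """Path length over sqrt(convex-hull area); NaN for degenerate hulls."""
    if path.n_points < 3:
        return float("nan")
    area = MultiPoint(path.points).convex_hull.area
    if not area > 0:
        return float("nan")
    return total_distance(path) / math.sqrt(area)


def rediscretize(points: np.ndarray, q: float) -> tuple:
    """Resample a polyline at constant chord length ``q``.

    Starting from the first vertex, each new vertex is the first point along
    the path at Euclidean distance exactly ``q`` from the previous one (the
    classical divider walk).  Returns the resampled vertices and the
    left-over chord from the last vertex to the path end (< q).
    """
    pts = np.asarray(points, dtype=float)
    if q <= 0:
        raise ValueError("q must be positive")
    if len(pts) < 2:
        return pts.copy(), 0.0
    out = [pts[0]]
    anchor = pts[0]
    seg, t0 = 0, 0.0
    n = len(pts)
    while True:
        hit = None
        s, t_lo = seg, t0
        while s < n - 1:
            a, b = pts[s], pts[s + 1]
            d = b - a
            f = a - anchor
            A = float(d @ d)
            if A > 0:
                B = 2.0 * float(f @ d)
                C = float(f @ f) - q * q
                disc = B * B - 4.0 * A * C
                if disc >= 0:
                    u = (-B + math.sqrt(disc)) / (2.0 * A)  # outward crossing
                    if t_lo < u <= 1.0:
                        hit = (s, u, a + u * d)
                        break
            s, t_lo = s + 1, 0.0
        if hit is None:
            break
        seg, t0, anchor = hit[0], hit[1], hit[2]
        out.append(anchor)
    remainder = float(np.hypot(*(pts[-1] - anchor)))
    return np.asarray(out), remainder


@dataclass(frozen=True)
class SinuosityParams:
    """Ingredients of the sinuosity index on a rediscretized path."""

    q: float  # rediscretization step, cm
    p: float  # mean step length after rediscretization, cm
    c: float  # mean cosine of turning angles
    b: float  # coefficient of variation of step length


def sinuosity_params(path: Path, q: float) -> SinuosityParams | None:
    """Rediscretize at step ``q`` and measure (p, c, b); None if too short."""
    pts, _ = rediscretize(path.points, q)
    if len(pts) < 3:
        return None
    steps = np.hypot(*np.diff(pts, axis=0).T)
    d = np.diff(pts, axis=0)
    headings = np.arctan2(d[:, 1], d[:, 0])
    c = float(np.mean(np.cos(_wrap_angle(np.diff(headings)))))
    p = float(steps.mean())
    b = float(steps.std() / p) if p > 0 else 0.0
    return SinuosityParams(q=q, p=p, c=c, b=b)


def sinuosity_from_params(params: SinuosityParams) -> float:
    """``S = 2 [p ((1+c)/(1-c) + b^2)]^(-1/2)``, with S -> 0 as c -> 1."""
    c = min(params.c, 1.0)
    if c >= 1.0 - 1e-12:
        return 0.0
    term = params.p * ((1.0 + c) / (1.0 - c) + params.b ** 2)
    if term <= 0:
        return float("nan")  # c == -1 with constant steps: index undefined
    return 2.0 / math.sqrt(term)


def sinuosity(path: Path, q: float = 5.0) -> float:
    """Scale-aware tortuosity (cm^-1/2) on the constant-step resampled path."""
    params = sinuosity_params(path, q)
    if params is None:
        return float("nan")
    return sinuosity_from_params(params)


def fractal_d(path: Path, divider_range: tuple = (2.0, 50.0),
              n_dividers: int = 10) -> float:
    """Fractal dimension of the path by the divider method.

    The path length ``L(eps) = n_steps * eps + remainder`` is measured by
    walking dividers of ``n_dividers`` log-spaced sizes along the path and
    ``D = 1 - slope`` of the least-squares fit of log L against log eps,
    clipped into [1, 2] with a warning.  A straight path has constant
    L(eps), hence D = 1.
    """
    eps_min, eps_max = divider_range
    if not (0 < eps_min < eps_max):
        raise ValueError("divider_range must satisfy 0 < eps_min < eps_max")
    if path.n_points < 2:
        return float("nan")
    eps_grid = np.geomspace(eps_min, eps_max, n_dividers)
    logs_e, logs_l = [], []
    for eps in eps_grid:
        pts, rem = rediscretize(path.points, eps)
        n_steps = len(pts) - 1
        if n_steps < 1:
            continue
        logs_e.append(math.log(eps))
        logs_l.append(math.log(n_steps * eps + rem))
    if len(logs_e) < 3:
        return float("nan")
    slope = np.polyfit(logs_e, logs_l, 1)[0]
    d = 1.0 - slope
    if not 1.0 - 1e-9 <= d <= 2.0 + 1e-9:
        warnings.warn(f"fractal D {d:.3f} outside [1, 2]; clipped", stacklevel=2)
    return float(min(2.0, max(1.0, d)))


# ---------------------------------------------------------------------------
# dog–robot interaction


def robot_interaction_features(dog: Path, robot, proximity_cm: float = 50.0) -> dict:
    """Distance-based interaction features of a dog trial with a toy robot.

    ``robot`` is either a fixed ``(x_cm, y_cm)`` position or a robot
    :class:`Path`, in which case its position is linearly interpolated onto
    the dog's time base.  An "approach" is a crossing below ``proximity_cm``,
    re-armed only after the dog retreats beyond 1.2x the radius (20%
    hysteresis, so jitter around the boundary is not counted repeatedly).
    """
    ids = ("robot_mean_dist_cm", "robot_min_dist_cm", "robot_time_within",
           "robot_n_approaches", "robot_latency_s")
    if robot is None or dog.n_points == 0:
        return {k: float("nan") for k in ids}
    if isinstance(robot, Path):
        if robot.n_points == 0:
            return {k: float("nan") for k in ids}
        rx = np.interp(dog.times_s, robot.times_s, robot.points[:, 0])
        ry = np.interp(dog.times_s, robot.times_s, robot.points[:, 1])
        rpos = np.column_stack([rx, ry])
    else:
        rpos = np.broadcast_to(np.asarray(robot, dtype=float), dog.points.shape)
    dist = np.hypot(*(dog.points - rpos).T)

    approaches, armed = 0, True
    for d in dist:
        if armed and d <= proximity_cm:
            approaches += 1
            armed = False
        elif not armed and d > 1.2 * proximity_cm:
            armed = True
    within = dist <= proximity_cm
    latency = (float(dog.times_s[within.argmax()] - dog.times_s[0])
               if within.any() else dog.duration_s)
    return {
        "robot_mean_dist_cm": float(dist.mean()),
        "robot_min_dist_cm": float(dist.min()),
        "robot_time_within": float(within.mean()),
        "robot_n_approaches": float(approaches),
        "robot_latency_s": latency,
    }


# ---------------------------------------------------------------------------
# assembly

E_FEATURE_IDS = (
    "total_distance_cm", "average_speed_cms", "straightness", "msd_mean_cm2",
    "intensity_of_use", "sinuosity", "fractal_d", "fraction_time_moving",
    "mean_abs_turn_rad", "turn_std_rad", "n_reversals", "room_coverage",
    "speed_p90_cms",
)
DR_FEATURE_IDS = E_FEATURE_IDS + (
    "robot_mean_dist_cm", "robot_min_dist_cm", "robot_time_within",
    "robot_n_approaches", "robot_latency_s",
)

#: Extra user-registered features: id -> callable(path, config) -> float.
EXTRA_FEATURES: dict = {}


def extract_features(traj: Trajectory, trial_type: str = "E",
                     config: FeatureConfig = FeatureConfig(),
                     room_cm=None, robot=None) -> FeatureVector:
    """Assemble the registered feature vector for one quality-passing trial.

    Exploration (E) trials get the locomotion and tortuosity features;
    dog–robot (DR) trials additionally get the interaction features.
    Deterministic given the inputs and config.  Undefined sub-features
    propagate as NaN with a recorded reason.
    """
    if trial_type not in ("E", "DR"):
        raise ValueError("trial_type must be 'E' or 'DR'")
    path = Path.from_trajectory(traj)
    values: dict[str, float] = {}
    missing: dict[str, str] = {}

    if path.n_points < config.min_points:
        ids = DR_FEATURE_IDS if trial_type == "DR" else E_FEATURE_IDS
        for k in ids:
            values[k] = float("nan")
            missing[k] = f"only {path.n_points} positions (< {config.min_points})"
        return FeatureVector(values=values, trial_type=trial_type, missing=missing)

    values["total_distance_cm"] = total_distance(path)
    values["average_speed_cms"] = average_speed(path)
    values["straightness"] = straightness(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, values["msd_mean_cm2"] = mean_squared_displacement(path, config.msd_lags_s)
        values["intensity_of_use"] = intensity_of_use(path)
        values["sinuosity"] = sinuosity(path, config.sinuosity_q_cm)
        values["fractal_d"] = fractal_d(path, config.fractal_eps_cm,
                                        config.fractal_n_dividers)
    values.update(locomotion_extras(path, config.move_threshold_cms,
                                    config.grid_cell_cm, room_cm))
    if trial_type == "DR":
        values.update(robot_interaction_features(path, robot, config.proximity_cm))
        if robot is None:
            for k in ("robot_mean_dist_cm", "robot_min_dist_cm",
                      "robot_time_within", "robot_n_approaches",
                      "robot_latency_s"):
                missing[k] = "no robot data for DR trial"
    for fid, fn in EXTRA_FEATURES.items():
        values[fid] = fn(path, config)

    for k, v in values.items():
        if isinstance(v, float) and math.isnan(v) and k not in missing:
            missing[k] = "undefined on this path"
    return FeatureVector(values=values, trial_type=trial_type, missing=missing)
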