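"""Synthetic consultation-room trajectories and tracker output.

A correlated random walk (CRW) stands in for dog locomotion: per frame
the heading is perturbed by a turning angle drawn from a wrapped-Cauchy
family with concentration ``kappa`` (mapped to the Cauchy rho as
``kappa / (1 + kappa)``), the step is speed x dt with multiplicative
log-normal noise, walls reflect specularly, and a two-state renewal
process inserts pauses.  An optional fixed robot exerts a heading drift.

Two regimes encode the qualitative clinical contrast: *calm* dogs move
slowly with persistent headings and frequent pauses; *hyperactive* dogs
move fast, turn sharply and rarely pause.  On top of the ground-truth
path, tracker noise is emulated — per-frame detection dropout, confidence
draws and position jitter — so the ingestion quality filters are
exercised.  Everything is reproducible from the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path as FilePath

import numpy as np
import pandas as pd

from .trajectory_io import RoomCalibration, write_detections

__all__ = [
    "SimConfig",
    "CohortSpec",
    "calm_config",
    "hyperactive_config",
    "default_calibration",
    "simulate_trajectory",
    "detections_frame",
    "simulate_cohort",
    "run_ladder",
    "parameter_recovery_report",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters for one behavioral regime."""

    regime: str = "calm"
    mean_speed_cms: float = 8.0
    speed_cv: float = 0.3
    kappa: float = 8.0            # turning concentration; larger = straighter
    pause_rate_per_s: float = 0.1
    mean_pause_s: float = 2.0
    room_cm: tuple = (340.0, 220.0)
    duration_s: float = 180.0
    fps: float = 30.0
    robot_cm: tuple | None = None       # (x, y)
    robot_attraction: float = 0.0       # heading drift weight in [0, 1]
    dropout_prob: float = 0.05
    confidence_mean: float = 0.9
    confidence_sd: float = 0.05
    position_jitter_cm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_speed_cms <= 0 or self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("speeds, durations and fps must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.pause_rate_per_s < 0 or self.mean_pause_s <= 0:
            raise ValueError("pause parameters must be positive")
        if min(self.room_cm) <= 0:
            raise ValueError("room dimensions must be positive")
        if not 0.0 <= self.robot_attraction <= 1.0:
            raise ValueError("robot_attraction must lie in [0, 1]")


def calm_config(**overrides) -> SimConfig:
    """Calm regime: slow, persistent heading, frequent pauses."""
    return replace(SimConfig(regime="calm", mean_speed_cms=8.0, kappa=8.0,
                             pause_rate_per_s=0.1), **overrides)


def hyperactive_config(**overrides) -> SimConfig:
    """Hyperactive regime: fast, erratic turning, almost no pauses."""
    return replace(SimConfig(regime="hyperactive", mean_speed_cms=30.0,
                             kappa=1.0, pause_rate_per_s=0.01), **overrides)


def default_calibration(room_cm=(340.0, 220.0), fps: float = 30.0,
                        image_px=(1280.0, 720.0)) -> RoomCalibration:
    """Calibration matching the default simulated room and camera."""
    return RoomCalibration(room_width_cm=room_cm[0], room_height_cm=room_cm[1],
                           image_width_px=image_px[0], image_height_px=image_px[1],
                           fps=fps)


def _wrapped_cauchy(rng: np.random.Generator, rho: float, n: int) -> np.ndarray:
    """Draw n wrapped-Cauchy turning angles centered on 0 with parameter rho."""
    if rho <= 0:
        return rng.uniform(-np.pi, np.pi, n)
    u = rng.random(n)
    scale = (1.0 - rho) / (1.0 + rho)
    return 2.0 * np.arctan(scale * np.tan(np.pi * (u - 0.5)))


def _wrap(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def simulate_trajectory(config: SimConfig,
                        rng: np.random.Generator | None = None) -> dict:
    """Run the CRW and emit tracker-style detections.

    Returns a dict with the ground-truth arrays (``x_cm``, ``y_cm``,
    ``times_s``, per-frame ``moving`` state) and ``detections`` — a
    DataFrame in the detections CSV dialect (pixel coordinates, empty bbox
    columns, confidences), with dropped frames absent.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w, h = config.room_cm
    dt = 1.0 / config.fps
    n = int(round(config.duration_s * config.fps))
    rho = config.kappa / (1.0 + config.kappa)

    turns = _wrapped_cauchy(rng, rho, n)
    # log-normal multiplicative speed noise with the requested CV
    sigma = math.sqrt(math.log(1.0 + config.speed_cv ** 2))
    speed_noise = rng.lognormal(-0.5 * sigma ** 2, sigma, n)
    u_pause = rng.random(n)
    u_resume = rng.random(n)

    x = np.empty(n)
    y = np.empty(n)
    moving = np.empty(n, dtype=bool)
    px, py = rng.uniform(0.2 * w, 0.8 * w), rng.uniform(0.2 * h, 0.8 * h)
    heading = rng.uniform(-math.pi, math.pi)
    p_pause = min(1.0, config.pause_rate_per_s * dt)
    p_resume = min(1.0, dt / config.mean_pause_s)
    is_moving = True

    for i in range(n):
        if is_moving and u_pause[i] < p_pause:
            is_moving = False
        elif not is_moving and u_resume[i] < p_resume:
            is_moving = True
        moving[i] = is_moving
        if is_moving:
            heading = _wrap(heading + turns[i])
            if config.robot_cm is not None and config.robot_attraction > 0:
                target = math.atan2(config.robot_cm[1] - py,
                                    config.robot_cm[0] - px)
                heading = _wrap(heading + config.robot_attraction
                                * _wrap(target - heading))
            step = config.mean_speed_cms * speed_noise[i] * dt
            px += step * math.cos(heading)
            py += step * math.sin(heading)
            # specular reflection keeps the speed distribution intact
            while not (0.0 <= px <= w and 0.0 <= py <= h):
                if px < 0.0:
                    px, heading = -px, _wrap(math.pi - heading)
                elif px > w:
                    px, heading = 2.0 * w - px, _wrap(math.pi - heading)
                if py < 0.0:
                    py, heading = -py, _wrap(-heading)
                elif py > h:
                    py, heading = 2.0 * h - py, _wrap(-heading)
        x[i], y[i] = px, py

    times = np.arange(n) / config.fps
    detected = rng.random(n) >= config.dropout_prob
    jitter = rng.normal(0.0, config.position_jitter_cm, (n, 2))
    confidence = np.clip(rng.normal(config.confidence_mean,
                                    config.confidence_sd, n), 0.0, 1.0)
    robot_conf = np.clip(rng.normal(config.confidence_mean,
                                    config.confidence_sd, n), 0.0, 1.0)

    cal = default_calibration(config.room_cm, config.fps)
    obs_x = np.clip(x + jitter[:, 0], 0.0, w)
    obs_y = np.clip(y + jitter[:, 1], 0.0, h)
    px_x, px_y = cal.cm_to_px(obs_x, obs_y)
    rows = {
        "frame": np.arange(n)[detected],
        "time_s": times[detected],
        "object": "dog",
        "x_px": np.round(px_x[detected], 3),
        "y_px": np.round(px_y[detected], 3),
        "x_min": "", "y_min": "", "x_max": "", "y_max": "",
        "confidence": np.round(confidence[detected], 4),
    }
    det = pd.DataFrame(rows)
    if config.robot_cm is not None:
        rx, ry = cal.cm_to_px(config.robot_cm[0], config.robot_cm[1])
        robot = pd.DataFrame({
            "frame": np.arange(n), "time_s": times, "object": "robot",
            "x_px": np.round(float(rx), 3), "y_px": np.round(float(ry), 3),
            "x_min": "", "y_min": "", "x_max": "", "y_max": "",
            "confidence": np.round(robot_conf, 4),
        })
        det = pd.concat([det, robot], ignore_index=True)
        det = det.sort_values(["frame", "object"], kind="stable").reset_index(drop=True)
    return {"x_cm": x, "y_cm": y, "times_s": times, "moving": moving,
            "detections": det, "calibration": cal}


def detections_frame(config: SimConfig) -> pd.DataFrame:
    return simulate_trajectory(config)["detections"]


@dataclass(frozen=True)
class CohortSpec:
    """A balanced synthetic cohort: n calm (C) and n hyperactive (H) dogs."""

    n_per_group: int = 19
    calm: SimConfig = field(default_factory=calm_config)
    hyperactive: SimConfig = field(default_factory=hyperactive_config)
    trial_types: tuple = ("E",)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if any(t not in ("E", "DR") for t in self.trial_types):
            raise ValueError("trial types must be 'E' and/or 'DR'")


def simulate_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Emit one detections CSV per (dog, trial) plus a manifest.

    Dogs ``H01..`` get the hyperactive config, ``C01..`` the calm one;
    per-dog seeds are spawned deterministically from the base seed.  DR
    trials place the robot at the room centre with a mild attraction.
    Returns the manifest (dog_id, group, trial_type, file, seed).
    """
    out = FilePath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(spec.base_seed).generate_state(
        2 * spec.n_per_group * len(spec.trial_types)) % (2 ** 31)
    rows = []
    i = 0
    for group, base_cfg in (("H", spec.hyperactive), ("C", spec.calm)):
        for d in range(spec.n_per_group):
            dog_id = f"{group}{d + 1:02d}"
            for trial in spec.trial_types:
                cfg = base_cfg
                if trial == "DR":
                    w, h = cfg.room_cm
                    cfg = replace(cfg, robot_cm=(w / 2.0, h / 2.0),
                                  robot_attraction=0.05)
                cfg = replace(cfg, seed=int(seeds[i]))
                i += 1
                fname = f"{dog_id}_{trial}.csv"
                write_detections(simulate_trajectory(cfg)["detections"],
                                 out / fname)
                rows.append({"dog_id": dog_id, "group": group,
                             "trial_type": trial, "file": fname,
                             "seed": cfg.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def _ladder_feature(config: SimConfig, feature: str) -> float:
    """Run one simulated trial through the ingestion path and featurize."""
    import tempfile

    from . import features as ft
    from . import trajectory_io as tio

    sim = simulate_trajectory(config)
    with tempfile.TemporaryDirectory() as td:
        path = FilePath(td) / "det.csv"
        write_detections(sim["detections"], path)
        traj = tio.read_detections(path, sim["calibration"])["dog"]
    traj = tio.smooth(tio.fill_gaps(traj, 15), 5)
    p = ft.Path.from_trajectory(traj)
    if feature == "average_speed_cms":
        return ft.average_speed(p)
    if feature == "sinuosity":
        return ft.sinuosity(p, 5.0)
    if feature == "fraction_time_moving":
        return ft.locomotion_extras(p)["fraction_time_moving"]
    raise ValueError(f"unknown ladder feature {feature!r}")


def run_ladder(param: str, values, feature: str, n_per_level: int = 10,
               duration_s: float = 60.0, base_seed: int = 0) -> pd.DataFrame:
    """Simulate a parameter ladder and measure the matched feature per dog.

    Each ladder level gets ``n_per_level`` independently seeded calm-base
    trials with ``param`` overridden; every trial runs through the full
    emission/ingestion/clean-up path before featurization, so recovery is
    measured under the generator's tracker-noise defaults.
    """
    seeds = np.random.SeedSequence(base_seed).generate_state(
        len(values) * n_per_level) % (2 ** 31)
    rows = []
    i = 0
    for v in values:
        for _ in range(n_per_level):
            cfg = replace(calm_config(duration_s=duration_s),
                          **{param: v, "seed": int(seeds[i])})
            i += 1
            rows.append({param: v, feature: _ladder_feature(cfg, feature)})
    return pd.DataFrame(rows)


def parameter_recovery_report(ladder: dict, feature_values: dict) -> pd.DataFrame:
    """Spearman association between a generator parameter and a feature.

    ``ladder`` maps parameter name -> per-dog parameter values;
    ``feature_values`` maps feature id -> matched per-dog feature values.
    A single-point ladder yields a degenerate report (NaN rho) with a
    warning.
    """
    import warnings
    from scipy.stats import spearmanr

    rows = []
    for (param, pvals), (feat, fvals) in zip(ladder.items(),
                                             feature_values.items()):
        pvals = np.asarray(pvals, dtype=float)
        fvals = np.asarray(fvals, dtype=float)
        if len(np.unique(pvals)) < 2:
            warnings.warn(f"degenerate ladder for {param}: single level",
                          stacklevel=2)
            rho = float("nan")
        else:
            rho = float(spearmanr(pvals, fvals).statistic)
        rows.append({"parameter": param, "feature": feat, "spearman_rho": rho,
                     "n": len(pvals), "n_levels": len(np.unique(pvals))})
    return pd.DataFrame(rows)
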