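"""Movement features: trivial geometry, brute-force oracles, invariances."""

import math
import warnings

import numpy as np
import pytest

from hscore.features import (FeatureConfig, Path, SinuosityParams,
                             average_speed, extract_features, fractal_d,
                             intensity_of_use, locomotion_extras,
                             mean_squared_displacement, rediscretize,
                             robot_interaction_features, sinuosity,
                             sinuosity_from_params, straightness,
                             total_distance)
from hscore.synthetic import calm_config, simulate_trajectory

from conftest import make_trajectory
from oracles import (chord_walk_brute, fractal_d_brute, hull_area_shoelace,
                     msd_brute, sinuosity_brute, total_distance_brute)


def path_from(points, dt=1.0 / 30.0):
    points = np.asarray(points, dtype=float)
    return Path(points=points, times_s=np.arange(len(points)) * dt)


class TestBasicLocomotion:
    def test_three_four_five_triangle(self):
        assert total_distance(path_from([(0, 0), (3, 4)])) == pytest.approx(5.0)

    def test_closed_unit_square_perimeter(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]
        assert total_distance(path_from(square)) == pytest.approx(4.0)

    def test_single_point_undefined(self):
        assert math.isnan(total_distance(path_from([(0, 0)])))

    def test_average_speed_plug_in(self):
        p = Path(points=[(0, 0), (5, 0)], times_s=[0.0, 2.0])
        assert average_speed(p) == pytest.approx(2.5)

    def test_stationary_speed_zero(self):
        p = Path(points=[(1, 1), (1, 1), (1, 1)], times_s=[0.0, 1.0, 2.0])
        assert average_speed(p) == 0.0

    def test_zero_elapsed_time_rejected(self):
        p = Path(points=[(0, 0), (1, 0)], times_s=[0.0, 0.0])
        with pytest.raises(ValueError):
            average_speed(p)

    def test_crw_speed_recovered_within_two_percent(self):
        cfg = calm_config(pause_rate_per_s=0.0, speed_cv=0.0, dropout_prob=0.0,
                          position_jitter_cm=0.0, duration_s=120.0, seed=11)
        sim = simulate_trajectory(cfg)
        p = Path(points=np.column_stack([sim["x_cm"], sim["y_cm"]]),
                 times_s=sim["times_s"])
        assert average_speed(p) == pytest.approx(cfg.mean_speed_cms, rel=0.02)


class TestStraightness:
    def test_collinear_path_is_one(self):
        assert straightness(path_from([(0, 0), (1, 0), (2, 0)])) == pytest.approx(1.0)

    def test_closed_loop_is_zero(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]
        assert straightness(path_from(square)) == pytest.approx(0.0)

    def test_matches_definition_oracle(self, random_path_factory):
        p = random_path_factory(5)
        expected = math.dist(p.points[0], p.points[-1]) / total_distance_brute(p.points)
        assert straightness(p) == pytest.approx(expected, abs=1e-12)


class TestMSD:
    def test_ballistic_closed_form(self):
        v, dt = 12.0, 1.0 / 30.0
        pts = [(v * dt * i, 0.0) for i in range(300)]
        curve, _ = mean_squared_displacement(path_from(pts, dt), [0.5, 1.0, 2.0])
        for tau, val in curve.items():
            assert val == pytest.approx(v * v * tau * tau, rel=1e-9)

    def test_stationary_is_zero(self):
        pts = [(3.0, 4.0)] * 100
        curve, summary = mean_squared_displacement(path_from(pts), [0.5, 1.0])
        assert all(v == 0.0 for v in curve.values())
        assert summary == 0.0

    def test_inadmissible_lag_omitted_with_warning(self):
        with pytest.warns(UserWarning, match="inadmissible"):
            curve, _ = mean_squared_displacement(path_from([(0, 0), (1, 0)]),
                                                 [1.0 / 30.0, 99.0])
        assert len(curve) == 1

    def test_matches_all_pairs_oracle(self, random_path_factory):
        p = random_path_factory(6)
        tau = 3.0 / 30.0  # 3 frames
        curve, _ = mean_squared_displacement(p, [tau])
        assert curve[tau] == pytest.approx(msd_brute(p.points, 3), rel=1e-12)

    def test_ballistic_msd_over_tau_squared_constant(self):
        v, dt = 7.0, 0.05
        pts = [(v * dt * i * 0.6, v * dt * i * 0.8) for i in range(200)]
        curve, _ = mean_squared_displacement(path_from(pts, dt), [0.5, 1.0, 2.0, 4.0])
        ratios = [val / tau ** 2 for tau, val in curve.items()]
        assert np.ptp(ratios) < 1e-6 * ratios[0]


class TestIntensityOfUse:
    def test_unit_square_perimeter_is_four(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]
        assert intensity_of_use(path_from(square)) == pytest.approx(4.0)

    def test_degenerate_paths_undefined(self):
        assert math.isnan(intensity_of_use(path_from([(0, 0), (1, 1)])))
        assert math.isnan(intensity_of_use(path_from([(0, 0), (1, 0), (2, 0)])))

    def test_matches_scipy_shoelace_oracle(self, random_path_factory):
        p = random_path_factory(7)
        expected = total_distance_brute(p.points) / math.sqrt(
            hull_area_shoelace(p.points))
        assert intensity_of_use(p) == pytest.approx(expected, rel=1e-9)


class TestSinuosity:
    def test_straight_path_limit_is_zero(self):
        pts = [(2.0 * i, 0.0) for i in range(100)]
        assert sinuosity(path_from(pts), q=5.0) == 0.0

    def test_plug_in_formula(self):
        params = SinuosityParams(q=1.0, p=1.0, c=0.0, b=0.0)
        assert sinuosity_from_params(params) == pytest.approx(2.0)

    def test_too_short_undefined(self):
        assert math.isnan(sinuosity(path_from([(0, 0), (1, 0)]), q=5.0))

    def test_rediscretized_steps_have_constant_length(self, random_path_factory):
        p = random_path_factory(8, n=120)
        pts, _ = rediscretize(p.points, 5.0)
        steps = np.hypot(*np.diff(pts, axis=0).T)
        np.testing.assert_allclose(steps, 5.0, atol=1e-9)

    def test_matches_independent_implementation(self, random_path_factory):
        p = random_path_factory(9, n=120)
        assert sinuosity(p, q=5.0) == pytest.approx(
            sinuosity_brute(p.points, 5.0), rel=1e-6)


class TestFractalD:
    def test_straight_line_dimension_one(self):
        pts = [(3.0 * i, 4.0 * i) for i in range(200)]
        assert fractal_d(path_from(pts), (2.0, 50.0), 10) == pytest.approx(
            1.0, abs=1e-6)

    def test_matches_independent_divider_walk(self, random_path_factory):
        p = random_path_factory(10, n=120)
        eps_grid = np.geomspace(2.0, 50.0, 10)
        assert fractal_d(p, (2.0, 50.0), 10) == pytest.approx(
            fractal_d_brute(p.points, eps_grid), abs=1e-6)

    def test_confined_dense_walk_is_plane_filling(self):
        rng = np.random.default_rng(12)
        pts = np.empty((4000, 2))
        pos = np.array([50.0, 50.0])
        for i in range(4000):  # unbiased jump walk confined to a 100 cm box
            pos = np.clip(pos + rng.normal(0, 8.0, 2), 0.0, 100.0)
            pts[i] = pos
        d = fractal_d(path_from(pts), (4.0, 40.0), 8)
        assert d > 1.5

    def test_invalid_range_rejected(self, random_path_factory):
        with pytest.raises(ValueError):
            fractal_d(random_path_factory(1), (50.0, 2.0), 10)


class TestLocomotionExtras:
    def test_stationary_path(self):
        pts = [(10.0, 10.0)] * 30
        out = locomotion_extras(path_from(pts), room_cm=(100.0, 100.0),
                                grid_cell=20.0)
        assert out["fraction_time_moving"] == 0.0
        assert out["room_coverage"] == pytest.approx(1 / 25)

    def test_straight_constant_speed(self):
        pts = [(5.0 * i, 0.0) for i in range(50)]
        out = locomotion_extras(path_from(pts))
        assert out["mean_abs_turn_rad"] == pytest.approx(0.0, abs=1e-12)
        assert out["n_reversals"] == 0

    def test_matches_brute_force(self, random_path_factory):
        p = random_path_factory(13)
        out = locomotion_extras(p, move_threshold=2.0, grid_cell=20.0,
                                room_cm=(340.0, 220.0))
        dt = np.diff(p.times_s)
        speeds = np.hypot(*np.diff(p.points, axis=0).T) / dt
        assert out["fraction_time_moving"] == pytest.approx(
            dt[speeds > 2.0].sum() / dt.sum())
        assert out["speed_p90_cms"] == pytest.approx(np.percentile(speeds, 90))
        headings = np.arctan2(*np.diff(p.points, axis=0).T[::-1])
        turns = np.angle(np.exp(1j * np.diff(headings)))
        assert out["mean_abs_turn_rad"] == pytest.approx(np.abs(turns).mean())
        assert out["n_reversals"] == (np.abs(turns) > np.pi / 2).sum()
        cells = {(int(x // 20.0), int(y // 20.0)) for x, y in p.points}
        assert out["room_coverage"] == pytest.approx(
            len(cells) / (math.ceil(340 / 20) * math.ceil(220 / 20)))


class TestRobotInteraction:
    def test_dog_at_robot(self):
        pts = [(50.0, 50.0)] * 60
        out = robot_interaction_features(path_from(pts), (50.0, 50.0), 50.0)
        assert out["robot_min_dist_cm"] == 0.0
        assert out["robot_time_within"] == 1.0
        assert out["robot_n_approaches"] >= 1
        assert out["robot_latency_s"] == 0.0

    def test_dog_always_far(self):
        pts = [(200.0, 0.0)] * 60
        p = path_from(pts)
        out = robot_interaction_features(p, (0.0, 0.0), 50.0)
        assert out["robot_time_within"] == 0.0
        assert out["robot_n_approaches"] == 0
        assert out["robot_latency_s"] == pytest.approx(p.duration_s)

    def test_distances_match_per_frame_oracle(self, random_path_factory):
        p = random_path_factory(14)
        robot = (170.0, 110.0)
        out = robot_interaction_features(p, robot, 50.0)
        dists = [math.dist(pt, robot) for pt in p.points]
        assert out["robot_mean_dist_cm"] == pytest.approx(np.mean(dists))
        assert out["robot_min_dist_cm"] == pytest.approx(min(dists))

    def test_hysteresis_debounces_boundary_jitter(self):
        # oscillate around the 50 cm radius without leaving the 60 cm band
        xs = [45.0, 55.0] * 5 + [100.0, 45.0]
        p = path_from([(x, 0.0) for x in xs])
        out = robot_interaction_features(p, (0.0, 0.0), 50.0)
        assert out["robot_n_approaches"] == 2

    def test_missing_robot_undefined(self, random_path_factory):
        out = robot_interaction_features(random_path_factory(15), None, 50.0)
        assert all(math.isnan(v) for v in out.values())


class TestInvariances:
    """Rigid motions leave features unchanged; scaling acts as expected."""

    INVARIANT = ("total_distance_cm", "straightness", "msd_mean_cm2",
                 "intensity_of_use", "sinuosity", "fractal_d",
                 "mean_abs_turn_rad", "turn_std_rad", "n_reversals")

    @staticmethod
    def _features(points):
        p = Path(points=points, times_s=np.arange(len(points)) / 30.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals = {
                "total_distance_cm": total_distance(p),
                "straightness": straightness(p),
                "msd_mean_cm2": mean_squared_displacement(p, [0.5, 1.0])[1],
                "intensity_of_use": intensity_of_use(p),
                "sinuosity": sinuosity(p, 5.0),
                "fractal_d": fractal_d(p, (2.0, 50.0), 8),
            }
            vals.update({k: locomotion_extras(p)[k] for k in
                         ("mean_abs_turn_rad", "turn_std_rad", "n_reversals")})
        return vals

    def test_rigid_motion_invariance(self, random_path_factory):
        base = random_path_factory(16).points
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = base @ rot.T + np.array([37.0, -12.0])
        a, b = self._features(base), self._features(moved)
        for k in self.INVARIANT:
            assert a[k] == pytest.approx(b[k], abs=1e-9), k

    def test_scale_equivariance(self, random_path_factory):
        base = random_path_factory(17).points
        k = 3.0
        p1 = Path(points=base, times_s=np.arange(len(base)) / 30.0)
        p2 = Path(points=base * k, times_s=np.arange(len(base)) / 30.0)
        assert total_distance(p2) == pytest.approx(k * total_distance(p1))
        assert straightness(p2) == pytest.approx(straightness(p1), abs=1e-12)
        m1 = mean_squared_displacement(p1, [0.5, 1.0])[1]
        m2 = mean_squared_displacement(p2, [0.5, 1.0])[1]
        assert m2 == pytest.approx(k * k * m1, rel=1e-9)
        # fractal D on the same *relative* divider grid
        d1 = fractal_d(p1, (2.0, 20.0), 8)
        d2 = fractal_d(p2, (2.0 * k, 20.0 * k), 8)
        assert d2 == pytest.approx(d1, abs=1e-9)

    def test_ranges(self, random_path_factory):
        for seed in range(5):
            v = self._features(random_path_factory(30 + seed).points)
            assert 0.0 <= v["straightness"] <= 1.0
            assert 1.0 <= v["fractal_d"] <= 2.0
            assert v["sinuosity"] >= 0.0
            assert v["total_distance_cm"] >= 0.0


class TestExtractFeatures:
    def test_all_exploration_features_finite(self):
        cfg = calm_config(seed=21, duration_s=60.0)
        sim = simulate_trajectory(cfg)
        traj = make_trajectory(sim["x_cm"], sim["y_cm"])
        fv = extract_features(traj, "E", room_cm=cfg.room_cm)
        assert fv.missing == {}
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_deterministic(self):
        cfg = calm_config(seed=22, duration_s=30.0)
        sim = simulate_trajectory(cfg)
        traj = make_trajectory(sim["x_cm"], sim["y_cm"])
        a = extract_features(traj, "E", room_cm=cfg.room_cm)
        b = extract_features(traj, "E", room_cm=cfg.room_cm)
        assert a.values == b.values

    def test_regime_contrast_in_key_features(self):
        from hscore.synthetic import hyperactive_config
        calm = simulate_trajectory(calm_config(seed=23, duration_s=60.0))
        hyper = simulate_trajectory(hyperactive_config(seed=23, duration_s=60.0))
        fc = extract_features(make_trajectory(calm["x_cm"], calm["y_cm"]), "E")
        fh = extract_features(make_trajectory(hyper["x_cm"], hyper["y_cm"]), "E")
        assert fh.values["total_distance_cm"] > fc.values["total_distance_cm"]
        assert fh.values["average_speed_cms"] > fc.values["average_speed_cms"]

    def test_short_path_marked_missing_with_reason(self):
        traj = make_trajectory([1.0, 2.0], [1.0, 2.0])
        fv = extract_features(traj, "E", FeatureConfig(min_points=10))
        assert all(math.isnan(v) for v in fv.values.values())
        assert all("positions" in r for r in fv.missing.values())

    def test_dr_without_robot_flags_interaction_features(self):
        cfg = calm_config(seed=24, duration_s=30.0)
        sim = simulate_trajectory(cfg)
        traj = make_trajectory(sim["x_cm"], sim["y_cm"])
        fv = extract_features(traj, "DR", room_cm=cfg.room_cm, robot=None)
        assert "robot_mean_dist_cm" in fv.missing
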