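import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moveson import (
    FeatureConfig,
    MovementStyleParams,
    curvature,
    directness_index,
    energy_index,
    gen_trajectory,
    kinematics,
    smoothness_index,
    speed,
    summarize,
)
from moveson.features import NoMotionError, _window_si
from moveson.trajectory_io import Trajectory

from conftest import make_powerlaw_spiral


def interior(a, n=10):
    return a[n:-n]


class TestSpeedAndEnergy:
    def test_straight_line_constant_speed(self, straight_traj):
        v = speed(straight_traj)
        np.testing.assert_allclose(interior(v), 0.5, atol=1e-9)

    def test_stationary_point_zero_speed(self):
        t = np.arange(100) / 180.0
        traj = Trajectory(t=t, x=np.full(100, 0.3), y=np.full(100, -0.2))
        np.testing.assert_allclose(speed(traj), 0.0, atol=1e-12)

    def test_circle_speed_matches_r_omega(self, circle_traj):
        v = speed(circle_traj)
        np.testing.assert_allclose(interior(v), 1.0, atol=1e-3)

    def test_energy_is_half_v_squared_exactly(self, circle_traj):
        v = speed(circle_traj)
        np.testing.assert_array_equal(energy_index(circle_traj), 0.5 * v**2)

    def test_energy_quadratic_homogeneity(self, straight_traj):
        doubled = Trajectory(t=straight_traj.t, x=2 * straight_traj.x,
                             y=2 * straight_traj.y, rate=straight_traj.rate)
        np.testing.assert_allclose(energy_index(doubled),
                                   4.0 * energy_index(straight_traj),
                                   rtol=1e-9)


class TestCurvature:
    def test_straight_line_zero_curvature(self, straight_traj):
        k = curvature(straight_traj)
        assert np.nanmax(np.abs(k)) < 1e-6

    def test_circle_curvature_is_inverse_radius(self, circle_traj):
        k = curvature(circle_traj)
        kv = np.abs(k[np.isfinite(k)])
        assert np.max(np.abs(kv - 1.25)) / 1.25 < 0.01

    def test_square_corners_dominate_edges(self):
        traj = gen_trajectory(MovementStyleParams(
            style="square", mean_speed=0.5, side=2.0, duration=16.0))
        k = np.abs(curvature(traj))
        k = k[np.isfinite(k)]
        edges = np.percentile(k, 50)        # straight legs: tiny curvature
        corners = np.max(k)
        assert corners > 10 * max(edges, 1e-12)

    def test_no_motion_raises(self):
        t = np.arange(100) / 180.0
        still = Trajectory(t=t, x=np.full(100, 1.0), y=np.zeros(100))
        with pytest.raises(NoMotionError):
            curvature(still)

    def test_matches_circumscribed_circle_oracle(self, spiral_traj):
        """Three-point circumcircle radius is an independent curvature
        estimate: k = 4*area / (|AB||BC||CA|)."""
        cfg = FeatureConfig()
        kin = kinematics(spiral_traj, cfg)
        x, y = spiral_traj.x, spiral_traj.y
        m = 4                                   # oracle stencil half-width
        idx = np.arange(m + 10, len(x) - m - 10, 7)
        ax, ay = x[idx - m], y[idx - m]
        bx, by = x[idx], y[idx]
        cx, cy = x[idx + m], y[idx + m]
        area2 = np.abs((bx - ax) * (cy - ay) - (by - ay) * (cx - ax))
        ab = np.hypot(bx - ax, by - ay)
        bc = np.hypot(cx - bx, cy - by)
        ca = np.hypot(ax - cx, ay - cy)
        k_oracle = 2.0 * area2 / (ab * bc * ca)
        ok = kin.valid[idx]
        rel = np.abs(np.abs(kin.k[idx][ok]) - k_oracle[ok]) / k_oracle[ok]
        assert np.max(rel) < 0.01


class TestSmoothness:
    def test_perfect_negative_linear_dependence(self):
        log_k = np.linspace(0.0, 1.0, 6)
        log_v = -0.5 * log_k + 0.2
        assert _window_si(log_k, log_v, "pearson") == pytest.approx(-1.0)

    def test_powerlaw_fixture_has_unit_correlation_windows(self, spiral_traj):
        _, si = smoothness_index(spiral_traj)
        valid = si[np.isfinite(si)]
        assert len(valid) > 200
        assert np.min(np.abs(valid)) >= 0.99
        assert np.mean(valid < 0) > 0.99        # negative coupling

    def test_independent_jitter_gives_weak_correlation(self):
        rng = np.random.default_rng(7)
        vals = [_window_si(rng.normal(size=5), rng.normal(size=5), "pearson")
                for _ in range(200)]
        assert np.mean(np.abs(vals)) < 0.5

    def test_pearson_variant_bounded(self):
        traj = gen_trajectory(MovementStyleParams(style="jerky", seed=11))
        _, si = smoothness_index(traj)
        valid = si[np.isfinite(si)]
        assert np.all(valid >= -1.0) and np.all(valid <= 1.0)

    def test_simplified_variant_positive_unbounded(self, spiral_traj):
        cfg = FeatureConfig(si_variant="simplified")
        _, si = smoothness_index(spiral_traj, cfg)
        valid = si[np.isfinite(si)]
        assert np.all(valid > 0.0)
        assert np.max(valid) > 1.0      # dimensional, not capped at 1

    def test_zero_variance_window_yields_nan_not_error(self):
        assert np.isnan(_window_si(np.zeros(5), np.ones(5), "pearson"))


class TestDirectness:
    def test_straight_polyline_is_one(self, straight_traj):
        assert directness_index(straight_traj) == pytest.approx(1.0, abs=1e-9)

    def test_closed_loop_is_zero(self):
        th = np.linspace(0, 2 * np.pi, 400)
        traj = Trajectory(t=np.linspace(0, 5, 400),
                          x=np.cos(th), y=np.sin(th))
        # force exact closure
        traj = Trajectory(t=traj.t, x=np.append(traj.x[:-1], traj.x[0]),
                          y=np.append(traj.y[:-1], traj.y[0]))
        assert directness_index(traj) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_path(self):
        n = 50
        t = np.linspace(0, 2, 2 * n - 1)
        x = np.concatenate([np.linspace(0, 1, n), np.full(n - 1, 1.0)])
        y = np.concatenate([np.zeros(n), np.linspace(0, 1, n)[1:]])
        traj = Trajectory(t=t, x=x, y=y)
        assert directness_index(traj) == pytest.approx(np.sqrt(2) / 2,
                                                       abs=1e-9)

    def test_zero_path_raises(self):
        t = np.arange(10) / 180.0
        with pytest.raises(NoMotionError):
            directness_index(Trajectory(t=t, x=np.ones(10), y=np.ones(10)))

    def test_bounded_by_one_on_random_walks(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(3, 40)
            t = np.arange(n) * 0.01
            x = np.cumsum(rng.normal(size=n))
            y = np.cumsum(rng.normal(size=n))
            traj = Trajectory(t=t, x=x, y=y)
            assert directness_index(traj) <= 1.0 + 1e-12


class TestInvariances:
    @settings(deadline=None, max_examples=25)
    @given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-3, 3),
           dy=st.floats(-3, 3))
    def test_di_rigid_motion_invariant(self, angle, dx, dy):
        traj = gen_trajectory(MovementStyleParams(style="smooth", seed=5))
        c, s = np.cos(angle), np.sin(angle)
        moved = Trajectory(t=traj.t, x=c * traj.x - s * traj.y + dx,
                           y=s * traj.x + c * traj.y + dy, rate=traj.rate)
        assert directness_index(moved) == pytest.approx(
            directness_index(traj), rel=1e-9)

    def test_curvature_translation_invariant_sign_flips_on_reflection(self):
        traj = gen_trajectory(MovementStyleParams(style="circle",
                                                  mean_speed=1.0, duration=5.0))
        shifted = Trajectory(t=traj.t, x=traj.x + 1.1, y=traj.y - 0.7,
                             rate=traj.rate)
        mirrored = Trajectory(t=traj.t, x=traj.x, y=-traj.y, rate=traj.rate)
        k = curvature(traj)
        np.testing.assert_allclose(curvature(shifted), k, atol=1e-9)
        np.testing.assert_allclose(curvature(mirrored), -k, atol=1e-9)

    def test_energy_translation_invariant(self, circle_traj):
        shifted = Trajectory(t=circle_traj.t, x=circle_traj.x + 2.0,
                             y=circle_traj.y + 1.0, rate=circle_traj.rate)
        np.testing.assert_allclose(energy_index(shifted),
                                   energy_index(circle_traj), atol=1e-12)


class TestSummarize:
    class Row:
        segment_id = "s1"
        sound_model = "S2"
        participant_id = "P3"
        group_id = "G1"
        session = 2
        observation_number = 9

    def test_constant_speed_straight_line_record(self, straight_traj):
        rec = summarize(straight_traj, self.Row())
        assert rec.EI_mean == pytest.approx(0.125, rel=1e-6)
        assert rec.DI == pytest.approx(1.0, abs=1e-9)
        assert np.isnan(rec.SI_mean)        # zero-variance windows
        assert rec.sound_model == "S2" and rec.observation_number == 9

    def test_matches_brute_force_window_means(self):
        traj = gen_trajectory(MovementStyleParams(style="smooth", seed=21))
        cfg = FeatureConfig()
        rec = summarize(traj, None, cfg)
        # independent re-aggregation from raw series
        edge = cfg.smooth_frames // 2 + 2
        ei_oracle = float(np.mean(energy_index(traj, cfg)[edge:-edge]))
        _, si = smoothness_index(traj, cfg)
        si_oracle = float(np.nanmean(si))
        assert rec.EI_mean == pytest.approx(ei_oracle, abs=1e-9)
        assert rec.SI_mean == pytest.approx(si_oracle, abs=1e-9)

    def test_deterministic(self):
        a = summarize(gen_trajectory(MovementStyleParams(style="jerky", seed=4)))
        b = summarize(gen_trajectory(MovementStyleParams(style="jerky", seed=4)))
        assert a == b


def test_powerlaw_oracle_correlation_equivalence(spiral_traj):
    """Windowed pearson SI must equal a hand-rolled correlation of the same
    log-curvature / log-speed values to 1e-9."""
    cfg = FeatureConfig()
    kin = kinematics(spiral_traj, cfg)
    centers, si = smoothness_index(spiral_traj, cfg)
    n_checked = 0
    win = cfg.si_window
    edges = kin.t[0] + win * np.arange(len(centers) + 1)
    bounds = np.searchsorted(kin.t, edges)
    for w in range(len(centers)):
        m = np.zeros(len(kin.t), dtype=bool)
        m[bounds[w]:bounds[w + 1]] = True
        m &= kin.valid & np.isfinite(kin.k) & (np.abs(kin.k) > cfg.k_floor)
        if m.sum() < 3:
            assert np.isnan(si[w])
            continue
        lk, lv = np.log(np.abs(kin.k[m])), np.log(kin.v[m])
        dk, dv = lk - lk.mean(), lv - lv.mean()
        num = np.mean(dk * dv)
        den = np.sqrt(np.mean(dk**2) * np.mean(dv**2))
        assert si[w] == pytest.approx(num / den, abs=1e-9)
        n_checked += 1
    assert n_checked >= 200
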