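import math

import numpy as np
import pytest

from dancekin.errors import FeatureError, LengthError, SchemaError
from dancekin.features import (
    AngularMomentumTrace,
    FeatureRegistry,
    angular_momentum_stats,
    angular_momentum_trace,
    ankle_height_stats,
    autocorr_peak_counts,
    bounce_features,
    default_registry,
    expandedness_stats,
    extract_features,
    extremity_acceleration,
    sacrum_jerkiness,
    sacrum_translation_stats,
    sharp_movement_counts,
)
from dancekin.kinematics import SacrumTrack, SmoothingConfig, differentiate, estimate_sacrum
from dancekin.motionsim import BASE_POSE
from dancekin.pose_io import COCO17, PoseSequence

from conftest import FPS, make_pose, static_pose

OFF = SmoothingConfig(enabled=False)


def _trace_from_series(series):
    """Wrap per-frame (N, 3) momentum sums as a single-joint trace."""
    L = np.asarray(series, float)[:, None, :]
    return AngularMomentumTrace(L=L, R=np.zeros_like(L))


class TestRegistry:
    def test_default_has_17_features(self):
        reg = default_registry()
        assert len(reg) == 17
        assert not reg.augmented

    def test_category_counts(self):
        reg = default_registry()
        counts = {}
        for spec in reg.specs:
            counts[spec.category] = counts.get(spec.category, 0) + 1
        assert counts == {"sacrum": 5, "extremities": 4, "angular_momentum": 6, "expandedness": 2}

    def test_augmented_appends_exactly_three(self):
        base, aug = default_registry(), default_registry(augmented=True)
        assert len(aug) == 20
        assert aug.names[:17] == base.names
        assert all(n.startswith("autocorr_peak_rate_") for n in aug.names[17:])

    def test_duplicate_names_rejected(self):
        spec = default_registry().specs[0]
        with pytest.raises(SchemaError):
            FeatureRegistry(specs=(spec, spec))


class TestSacrumJerkiness:
    def test_static_zero(self):
        assert sacrum_jerkiness(np.zeros((50, 3))) == 0.0

    def test_cubic_closed_form(self):
        # x(t) = a t^3 has constant jerk 6a; third forward difference is exact
        a = 0.5
        t = np.arange(120) / FPS
        pos = np.zeros((120, 3))
        pos[:, 0] = a * t**3
        stack = differentiate(pos, FPS, OFF)
        assert sacrum_jerkiness(stack.jerk[:, 0, :]) == pytest.approx(6 * a, rel=1e-6)

    def test_sinusoid_quadrature_oracle(self):
        A, f, dur = 0.05, 2.0, 20.0
        t = np.arange(int(dur * FPS)) / FPS
        pos = np.zeros((len(t), 3))
        pos[:, 1] = A * np.sin(2 * np.pi * f * t)
        stack = differentiate(pos, FPS, OFF)
        got = sacrum_jerkiness(stack.jerk[:, 0, :])
        # independent oracle: mean |A w^3 cos(w t)| by dense quadrature
        w = 2 * np.pi * f
        tt = np.linspace(0, dur, 200001)
        expected = np.trapezoid(np.abs(A * w**3 * np.cos(w * tt)), tt) / dur
        assert got == pytest.approx(expected, rel=0.02)


class TestAnkleHeight:
    def test_constant_ankles(self):
        arr = np.zeros((10, 17, 3))
        arr[:, [15, 16], 1] = 0.07
        mean, sd = ankle_height_stats(make_pose(arr))
        assert (mean, sd) == (0.0, 0.0)

    def test_asymmetric_constant(self):
        arr = np.zeros((10, 17, 3))
        arr[:, 16, 1] = 0.2  # right ankle fixed high, left at 0
        mean, sd = ankle_height_stats(make_pose(arr))
        assert mean == pytest.approx(0.1, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_oscillating_ankle_brute_force(self):
        n = 600  # whole periods at 1 Hz
        t = np.arange(n) / FPS
        arr = np.zeros((n, 17, 3))
        right = 0.1 * (1 + np.sin(2 * np.pi * t))
        arr[:, 16, 1] = right
        mean, sd = ankle_height_stats(make_pose(arr))
        # brute-force per-frame oracle of the stated formula
        floor = min(min(0.0, r) for r in right)
        h = [(0.0 + r) / 2 - floor for r in right]
        assert mean == pytest.approx(np.mean(h), abs=1e-12)
        assert sd == pytest.approx(np.std(h), abs=1e-12)


class TestExtremityAcceleration:
    def test_static_zero(self):
        pose = static_pose(60)
        stack = differentiate(pose.positions, FPS, OFF)
        assert extremity_acceleration(stack, pose, "wrists") == 0.0

    def test_constant_acceleration(self):
        t = np.arange(60) / FPS
        arr = np.zeros((60, 17, 3))
        arr[:, [9, 10], 0] = (0.5 * 1.0 * t**2)[:, None]
        pose = make_pose(arr)
        stack = differentiate(pose.positions, FPS, OFF)
        assert extremity_acceleration(stack, pose, "wrists") == pytest.approx(1.0, rel=1e-9)

    def test_circular_wrist_centripetal(self):
        r, w = 0.4, 2 * np.pi
        t = np.arange(600) / FPS
        arr = np.zeros((600, 17, 3))
        arr[:, 9, 0] = r * np.cos(w * t)
        arr[:, 9, 2] = r * np.sin(w * t)
        pose = make_pose(arr)
        stack = differentiate(pose.positions, FPS, OFF)
        # one wrist at centripetal accel r w^2, the other static -> half
        assert extremity_acceleration(stack, pose, "wrists") == pytest.approx(
            0.5 * r * w**2, rel=0.02
        )


class TestAngularMomentum:
    def test_static_zero(self):
        pose = static_pose(60)
        stack = differentiate(pose.positions, FPS, OFF)
        trace = angular_momentum_trace(pose, estimate_sacrum(pose), stack)
        np.testing.assert_allclose(trace.L, 0.0, atol=1e-12)
        assert angular_momentum_stats(trace) == (0.0, 0.0, 0.0)

    def test_circling_joint_closed_form(self):
        r, w = 0.5, np.pi
        t = np.arange(600) / FPS
        arr = np.zeros((600, 17, 3))
        # hips at origin -> sacrum at origin; nose circles clockwise in X-Z
        arr[:, 0, 0] = r * np.cos(w * t)
        arr[:, 0, 2] = -r * np.sin(w * t)
        pose = make_pose(arr)
        stack = differentiate(pose.positions, FPS, OFF)
        trace = angular_momentum_trace(pose, estimate_sacrum(pose), stack)
        L_nose = trace.L[:, 0, :]
        # closed form for circular motion: |L| = r^2 w along +y (right-hand rule)
        assert np.mean(L_nose[:, 1]) == pytest.approx(r**2 * w, rel=0.02)
        assert np.max(np.abs(L_nose[:, [0, 2]])) < 0.02 * r**2 * w

    def test_orthogonality_invariant(self):
        rng = np.random.default_rng(3)
        pose = make_pose(rng.normal(size=(50, 17, 3)))
        stack = differentiate(pose.positions, FPS, OFF)
        trace = angular_momentum_trace(pose, estimate_sacrum(pose), stack)
        dots = np.einsum("ijk,ijk->ij", trace.L, trace.R)
        assert np.max(np.abs(dots)) < 1e-9

    def test_rigid_spin_flat_body(self):
        # joints in the sacrum's horizontal plane: mean |L| = mean r^2 w and
        # the vertical component carries all of it
        w = 1.3
        t = np.arange(600) / FPS
        radii = np.linspace(0.2, 1.0, 17)
        angles0 = np.linspace(0, 2 * np.pi, 17, endpoint=False)
        arr = np.zeros((600, 17, 3))
        for j in range(17):
            arr[:, j, 0] = radii[j] * np.cos(angles0[j] + w * t)
            arr[:, j, 2] = radii[j] * np.sin(angles0[j] + w * t)
        arr[:, [11, 12], :] = 0.0  # hips at the axis -> sacrum at origin
        pose = make_pose(arr)
        stack = differentiate(pose.positions, FPS, OFF)
        trace = angular_momentum_trace(pose, estimate_sacrum(pose), stack)
        mean_mag, _, rotation = angular_momentum_stats(trace)
        radii[[11, 12]] = 0.0
        expected = np.mean(radii**2) * w
        assert mean_mag == pytest.approx(expected, rel=0.01)
        assert rotation == pytest.approx(mean_mag, rel=0.01)

    def test_cartwheel_axis_bookkeeping(self):
        # rigid rotation about the X axis: no vertical angular momentum, so the
        # default horizontal-rotation reading is ~0 while the literal X-Z
        # variant recovers the full magnitude
        w = 1.0
        t = np.arange(600) / FPS
        arr = np.zeros((600, 17, 3))
        radii = np.linspace(0.3, 0.8, 17)
        for j in range(17):
            arr[:, j, 1] = radii[j] * np.cos(w * t)
            arr[:, j, 2] = radii[j] * np.sin(w * t)
        arr[:, [11, 12], :] = 0.0
        pose = make_pose(arr)
        stack = differentiate(pose.positions, FPS, OFF)
        trace = angular_momentum_trace(pose, estimate_sacrum(pose), stack)
        mean_mag, _, rot_default = angular_momentum_stats(trace)
        _, _, rot_literal = angular_momentum_stats(trace, literal_xz=True)
        assert mean_mag > 0.05
        assert rot_default < 0.01 * mean_mag
        assert rot_literal == pytest.approx(mean_mag, rel=0.01)


class TestSharpMovements:
    def test_constant_series_zero(self):
        trace = _trace_from_series(np.ones((600, 3)) * 2.0)
        assert sharp_movement_counts(trace, FPS) == (0.0, 0.0, 0.0)

    def test_injected_bumps_counted(self):
        n = 600  # 10 s
        t = np.arange(n) / FPS
        series = np.zeros((n, 3))
        background = 0.01 * np.sin(2 * np.pi * 0.3 * t)  # smooth low drift
        bg_sd = np.std(background)
        series[:, 1] = background
        centers = np.linspace(40, 560, 7).astype(int)
        bump = np.exp(-0.5 * (np.arange(-6, 7) / 2.0) ** 2)  # Gaussian bump
        for c in centers:
            series[c - 6 : c + 7, 1] += 10 * bg_sd * bump  # amplitude 10x bg SD
        trace = _trace_from_series(series)
        _, rate_y, _ = sharp_movement_counts(trace, FPS)
        assert rate_y == pytest.approx(0.7, abs=1e-9)  # 7 bumps known by construction

    def test_sinusoid_two_peaks_per_period(self):
        n = 600
        t = np.arange(n) / FPS
        series = np.zeros((n, 3))
        series[:, 1] = np.sin(2 * np.pi * 1.0 * t)
        trace = _trace_from_series(series)
        _, rate_y, _ = sharp_movement_counts(trace, FPS)
        # brute-force local-maximum scan of |s| as the oracle
        s = np.abs(series[:, 1])
        count = sum(1 for i in range(1, n - 1) if s[i] > s[i - 1] and s[i] > s[i + 1])
        assert rate_y == pytest.approx(count / 10.0, abs=1e-9)
        assert rate_y == pytest.approx(2.0, abs=0.05)


class TestExpandedness:
    def test_coincident_joints(self):
        pose = make_pose(np.zeros((10, 17, 3)))
        assert expandedness_stats(pose, estimate_sacrum(pose)) == (0.0, 0.0)

    def test_constant_distance_one(self):
        arr = np.zeros((10, 17, 3))
        arr[:, :, 0] = 1.0
        arr[:, [11, 12], 0] = 0.0
        arr[:, [11, 12], 2] = [-1.0, 1.0]  # hips symmetric -> sacrum origin, dist 1
        pose = make_pose(arr)
        mean, sd = expandedness_stats(pose, estimate_sacrum(pose))
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_homogeneity(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(20, 17, 3))
        pose = make_pose(arr)
        scaled = make_pose(3.5 * arr)
        m1, s1 = expandedness_stats(pose, estimate_sacrum(pose))
        m2, s2 = expandedness_stats(scaled, estimate_sacrum(scaled))
        assert m2 == pytest.approx(3.5 * m1, rel=1e-12)
        assert s2 == pytest.approx(3.5 * s1, rel=1e-12)


class TestSacrumTranslation:
    def test_static(self):
        track = SacrumTrack(np.zeros((60, 3)))
        vel = np.zeros((57, 3))
        assert sacrum_translation_stats(track, vel) == (0.0, 0.0)

    def test_uniform_glide_3_4_5(self):
        t = np.arange(60)[:, None] / FPS
        pos = t * np.array([0.3, 0.0, 0.4])
        stack = differentiate(pos, FPS, OFF)
        track = SacrumTrack(pos)
        speed, _ = sacrum_translation_stats(track, stack.velocity[:, 0, :])
        assert speed == pytest.approx(0.5, rel=1e-9)

    def test_vertical_sine_height_sd(self):
        A = 0.07
        t = np.arange(600) / FPS  # whole periods
        pos = np.zeros((600, 3))
        pos[:, 1] = A * np.sin(2 * np.pi * 1.0 * t)
        _, height_sd = sacrum_translation_stats(SacrumTrack(pos), np.zeros((597, 3)))
        assert height_sd == pytest.approx(A / math.sqrt(2), rel=0.01)


class TestBounce:
    def test_pure_sine(self):
        t = np.arange(600) / FPS
        pos = np.zeros((600, 3))
        pos[:, 1] = 0.05 * np.sin(2 * np.pi * 2.0 * t)
        freq, reg = bounce_features(SacrumTrack(pos), FPS)
        assert freq == pytest.approx(2.0, abs=FPS / 600)  # one bin
        assert reg > 0.95

    def test_constant_series(self):
        freq, reg = bounce_features(SacrumTrack(np.full((300, 3), 0.9)), FPS)
        assert (freq, reg) == (0.0, 0.0)

    def test_white_noise_low_regularity(self):
        rng = np.random.default_rng(11)
        pos = np.zeros((600, 3))
        pos[:, 1] = rng.normal(0, 1, 600)
        _, reg = bounce_features(SacrumTrack(pos), FPS)
        assert reg < 0.3

    def test_too_short(self):
        with pytest.raises(LengthError):
            bounce_features(SacrumTrack(np.zeros((60, 3))), FPS)


class TestAutocorrPeaks:
    def test_constant_series_zero(self):
        trace = _trace_from_series(np.full((600, 3), 1.5))
        assert autocorr_peak_counts(trace, FPS) == (0, 0, 0)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(4)
        trace = _trace_from_series(rng.normal(size=(600, 3)))
        counts = autocorr_peak_counts(trace, FPS)
        assert all(c <= 1 for c in counts)

    def test_periodic_counts_match_lag_window(self):
        n = 600  # 10 s; lag window 5 s holds 10 periods at 2 Hz
        t = np.arange(n) / FPS
        series = np.zeros((n, 3))
        series[:, 1] = np.sin(2 * np.pi * 2.0 * t)
        trace = _trace_from_series(series)
        _, n_y, _ = autocorr_peak_counts(trace, FPS)
        assert abs(n_y - 10) <= 1

    def test_too_short(self):
        with pytest.raises(LengthError):
            autocorr_peak_counts(_trace_from_series(np.zeros((100, 3))), FPS)


class TestExtractFeatures:
    def test_default_gives_17_finite_values(self):
        rng = np.random.default_rng(0)
        arr = np.broadcast_to(BASE_POSE, (600, 17, 3)) + rng.normal(0, 0.01, (600, 17, 3))
        fv = extract_features(make_pose(arr))
        assert len(fv.values) == 17
        assert tuple(fv.values) == default_registry().names
        assert all(math.isfinite(v) for v in fv.values.values())

    def test_static_pose_zeros_dynamic_features(self):
        fv = extract_features(static_pose(300), smoothing=OFF)
        static_exp = np.linalg.norm(
            BASE_POSE - 0.5 * (BASE_POSE[11] + BASE_POSE[12]), axis=1
        )
        assert fv.values["expandedness_mean"] == pytest.approx(static_exp.mean(), rel=1e-9)
        for name in (
            "sacrum_xz_speed_mean", "sacrum_height_sd", "sacrum_jerkiness",
            "wrist_accel_mean", "ankle_accel_mean", "angmom_mean_mag",
            "sharp_rate_x", "sharp_rate_y", "sharp_rate_z",
        ):
            assert fv.values[name] == pytest.approx(0.0, abs=1e-9)

    def test_augmented_gives_20(self):
        rng = np.random.default_rng(1)
        arr = np.broadcast_to(BASE_POSE, (600, 17, 3)) + rng.normal(0, 0.01, (600, 17, 3))
        fv = extract_features(make_pose(arr), registry=default_registry(augmented=True))
        assert len(fv.values) == 20

    def test_failure_names_feature(self):
        # 100 frames < 2 s: bounce features cannot be computed
        with pytest.raises(FeatureError, match="bounce"):
            extract_features(static_pose(100), smoothing=OFF)

    def test_tiling_periodic_sequence_stable(self):
        # doubling a whole-period sequence leaves averaged features ~unchanged
        from dancekin.motionsim import MotionSpec, generate_motion

        spec = MotionSpec(duration=10, bounce_amplitude=0.04, bounce_frequency=2.0,
                          spin_rate=np.pi, seed=0)
        seq = generate_motion(spec)
        tiled = make_pose(np.concatenate([seq.positions, seq.positions]), fps=seq.fps)
        fv1 = extract_features(seq, smoothing=OFF)
        fv2 = extract_features(tiled, smoothing=OFF)
        for name in ("sacrum_jerkiness", "sacrum_height_sd", "wrist_accel_mean",
                     "angmom_mean_mag", "horizontal_rotation", "expandedness_mean",
                     "bounce_frequency"):
            assert fv2.values[name] == pytest.approx(fv1.values[name], rel=0.02), name
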