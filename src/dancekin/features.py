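"""The interpretable movement encoding.

A pose sequence is summarized by 17 macroscopic features in four categories:

* **sacrum** — planar travel speed, vertical-position SD, jerkiness (mean
  jerk magnitude), dominant bounce frequency, and bounce regularity
  (autocorrelation first-peak height of the vertical sacrum series);
* **extremities** — mean wrist and ankle acceleration magnitude, and the
  mean and SD of ankle height above the estimated floor;
* **angular momentum** — mean and SD of the per-joint, unit-mass angular
  momentum magnitude about the sacrum (L = R x V), the mean vertical
  component (horizontal rotation), and per-axis rates of prominent peaks in
  the joint-summed momentum trace ("sharp movements");
* **expandedness** — mean and SD of joint-to-sacrum distance.

An augmented registry appends three rhythm features: per-axis counts of
prominent peaks in the autocorrelation of the angular-momentum trace,
normalized to rates so sequence duration does not leak into the encoding.

Population (ddof=0) standard deviations are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import FeatureError, LayoutError, LengthError, SchemaError
from .kinematics import (
    DerivativeStack,
    SacrumTrack,
    SmoothingConfig,
    differentiate,
    estimate_sacrum,
)
from .pose_io import PoseSequence

__all__ = [
    "FeatureSpec",
    "FeatureRegistry",
    "FeatureVector",
    "FeatureMatrix",
    "AngularMomentumTrace",
    "default_registry",
    "registry_from_names",
    "sacrum_jerkiness",
    "ankle_height_stats",
    "extremity_acceleration",
    "angular_momentum_trace",
    "angular_momentum_stats",
    "sharp_movement_counts",
    "expandedness_stats",
    "sacrum_translation_stats",
    "bounce_features",
    "autocorr_peak_counts",
    "extract_features",
]

CATEGORIES = ("sacrum", "extremities", "angular_momentum", "expandedness")


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    category: str
    units: str
    description: str


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered list of feature specifications; data, so alternates are pluggable."""

    specs: tuple[FeatureSpec, ...]
    augmented: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique within a registry")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def __len__(self) -> int:
        return len(self.specs)


_DEFAULT_SPECS: tuple[FeatureSpec, ...] = (
    # sacrum (5)
    FeatureSpec("sacrum_xz_speed_mean", "sacrum", "m/s", "mean sacrum speed in the floor plane"),
    FeatureSpec("sacrum_height_sd", "sacrum", "m", "SD of the sacrum's vertical position"),
    FeatureSpec("sacrum_jerkiness", "sacrum", "m/s^3", "mean magnitude of sacrum jerk"),
    FeatureSpec("bounce_frequency", "sacrum", "Hz", "dominant frequency of vertical sacrum motion"),
    FeatureSpec(
        "bounce_regularity", "sacrum", "unitless",
        "autocorrelation first-peak height of vertical sacrum motion, in [0, 1]",
    ),
    # extremities (4)
    FeatureSpec("wrist_accel_mean", "extremities", "m/s^2", "mean wrist acceleration magnitude"),
    FeatureSpec("ankle_accel_mean", "extremities", "m/s^2", "mean ankle acceleration magnitude"),
    FeatureSpec("ankle_height_mean", "extremities", "m", "mean ankle height above the floor"),
    FeatureSpec("ankle_height_sd", "extremities", "m", "SD of ankle height above the floor"),
    # angular momentum (6)
    FeatureSpec("angmom_mean_mag", "angular_momentum", "m^2/s", "mean |L| about the sacrum"),
    FeatureSpec("angmom_sd_mag", "angular_momentum", "m^2/s", "SD of |L| about the sacrum"),
    FeatureSpec(
        "horizontal_rotation", "angular_momentum", "m^2/s",
        "mean magnitude of the vertical angular-momentum component",
    ),
    FeatureSpec("sharp_rate_x", "angular_momentum", "1/s", "prominent-peak rate, x momentum trace"),
    FeatureSpec("sharp_rate_y", "angular_momentum", "1/s", "prominent-peak rate, y momentum trace"),
    FeatureSpec("sharp_rate_z", "angular_momentum", "1/s", "prominent-peak rate, z momentum trace"),
    # expandedness (2)
    FeatureSpec("expandedness_mean", "expandedness", "m", "mean joint-to-sacrum distance"),
    FeatureSpec("expandedness_sd", "expandedness", "m", "SD of joint-to-sacrum distance"),
)

_AUGMENTED_SPECS: tuple[FeatureSpec, ...] = tuple(
    FeatureSpec(
        f"autocorr_peak_rate_{ax}", "angular_momentum", "1/s",
        f"rate of prominent autocorrelation peaks, {ax} momentum trace",
    )
    for ax in ("x", "y", "z")
)


def default_registry(augmented: bool = False) -> FeatureRegistry:
    """The standard 17-feature registry, or the 20-feature augmented variant."""
    specs = _DEFAULT_SPECS + (_AUGMENTED_SPECS if augmented else ())
    return FeatureRegistry(specs=specs, augmented=augmented)


def registry_from_names(names) -> FeatureRegistry:
    """Rebuild a registry from feature-column names (used when reading tables)."""
    known = {s.name: s for s in _DEFAULT_SPECS + _AUGMENTED_SPECS}
    specs = tuple(
        known.get(n, FeatureSpec(n, "sacrum", "unknown", "restored from table")) for n in names
    )
    augmented = {a.name for a in _AUGMENTED_SPECS}.issubset(set(names))
    return FeatureRegistry(specs=specs, augmented=augmented)


@dataclass
class AngularMomentumTrace:
    """Per-frame, per-joint unit-mass angular momentum about the sacrum.

    ``L[i, j] = R[i, j] x V[i, j]`` where ``R`` is the joint position
    relative to the sacrum and ``V`` the joint velocity; both ``(N', J, 3)``.
    """

    L: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        if self.L.shape != self.R.shape:
            raise ValueError("L and R must share a shape")

    @property
    def n_frames(self) -> int:
        return self.L.shape[0]


@dataclass
class FeatureVector:
    values: dict[str, float]
    sequence_id: str
    genre: str | None = None
    tier: str | None = None

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise FeatureError(f"{self.sequence_id}: non-finite feature values for {bad}")

    def as_array(self, names) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)


@dataclass
class FeatureMatrix:
    rows: list[FeatureVector]
    registry: FeatureRegistry

    def __post_init__(self) -> None:
        if not self.rows:
            raise SchemaError("feature matrix needs at least one row")
        expected = set(self.registry.names)
        for row in self.rows:
            if set(row.values) != expected:
                raise SchemaError(f"{row.sequence_id}: feature keys do not match registry")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.registry.names

    def X(self) -> np.ndarray:
        """Feature values as an ``(n_rows, n_features)`` array in registry order."""
        return np.array([r.as_array(self.registry.names) for r in self.rows])

    def labels(self) -> list[str | None]:
        return [r.genre for r in self.rows]

    def to_dataframe(self):
        import pandas as pd

        data = {
            "sequence_id": [r.sequence_id for r in self.rows],
            "genre": [r.genre for r in self.rows],
            "tier": [r.tier for r in self.rows],
        }
        for name in self.registry.names:
            data[name] = [r.values[name] for r in self.rows]
        return pd.DataFrame(data)

    def subset(self, keep) -> "FeatureMatrix":
        keep = list(keep)
        specs = tuple(s for s in self.registry.specs if s.name in keep)
        registry = FeatureRegistry(specs=specs, augmented=self.registry.augmented)
        rows = [
            FeatureVector(
                values={n: r.values[n] for n in registry.names},
                sequence_id=r.sequence_id,
                genre=r.genre,
                tier=r.tier,
            )
            for r in self.rows
        ]
        return FeatureMatrix(rows=rows, registry=registry)


# ---------------------------------------------------------------------------
# Individual feature computations
# ---------------------------------------------------------------------------


def _pop_sd(x: np.ndarray) -> float:
    return float(np.std(x))


def sacrum_jerkiness(sacrum_jerk: np.ndarray) -> float:
    """Mean Euclidean norm of the sacrum's jerk over valid frames (m/s^3)."""
    sacrum_jerk = np.asarray(sacrum_jerk, dtype=float)
    if sacrum_jerk.shape[0] < 1:
        raise LengthError("empty jerk series")
    return float(np.linalg.norm(sacrum_jerk, axis=-1).mean())


def ankle_height_stats(pose: PoseSequence) -> tuple[float, float]:
    """Mean and SD of ankle height above the floor.

    The floor is the minimum vertical coordinate either ankle reaches over
    the whole sequence; per-frame height is the two ankles' mean vertical
    coordinate minus the floor.
    """
    roles = pose.layout.role_index
    try:
        la, ra = roles["left_ankle"], roles["right_ankle"]
    except KeyError as exc:  # pragma: no cover
        raise LayoutError("layout must define both ankle roles") from exc
    v = pose.layout.vertical_axis
    ankles_y = pose.positions[:, [la, ra], v]
    floor = float(ankles_y.min())
    height = ankles_y.mean(axis=1) - floor
    return float(height.mean()), _pop_sd(height)


def extremity_acceleration(stack: DerivativeStack, pose: PoseSequence, role_pair: str) -> float:
    """Mean acceleration magnitude over the two wrists or two ankles (m/s^2)."""
    pair = {"wrists": ("left_wrist", "right_wrist"), "ankles": ("left_ankle", "right_ankle")}
    if role_pair not in pair:
        raise LayoutError(f"role_pair must be 'wrists' or 'ankles', got {role_pair!r}")
    idx = [pose.layout.role_index[r] for r in pair[role_pair]]
    acc = stack.acceleration[:, idx, :]
    return float(np.linalg.norm(acc, axis=-1).mean())


def angular_momentum_trace(
    pose: PoseSequence, sacrum: SacrumTrack, stack: DerivativeStack
) -> AngularMomentumTrace:
    """Unit-mass angular momentum of every joint about the sacrum.

    The hips count as joints; the synthetic sacrum itself does not (the
    COCO layout has no sacrum keypoint).
    """
    n = stack.n_frames
    if sacrum.positions.shape[0] < n or pose.positions.shape[0] < n:
        raise LengthError("sacrum/pose shorter than the derivative valid range")
    R = pose.positions[:n] - sacrum.positions[:n, None, :]
    L = np.cross(R, stack.velocity)
    return AngularMomentumTrace(L=L, R=R)


def angular_momentum_stats(
    trace: AngularMomentumTrace, vertical_axis: int = 1, literal_xz: bool = False
) -> tuple[float, float, float]:
    """Mean and SD of |L|, plus the horizontal-rotation summary.

    Rotation in the floor plane produces angular momentum along the
    vertical axis, so by default horizontal rotation is the mean |L_y|.
    ``literal_xz=True`` instead averages the magnitude of the (x, z)
    components, the alternative axis-bookkeeping convention.
    """
    if trace.n_frames < 1:
        raise LengthError("empty angular-momentum trace")
    mag = np.linalg.norm(trace.L, axis=-1)
    if literal_xz:
        horiz_axes = [a for a in (0, 1, 2) if a != vertical_axis]
        rotation = float(np.linalg.norm(trace.L[..., horiz_axes], axis=-1).mean())
    else:
        rotation = float(np.abs(trace.L[..., vertical_axis]).mean())
    return float(mag.mean()), _pop_sd(mag), rotation


def sharp_movement_counts(
    trace: AngularMomentumTrace, fps: float, prominence: float = 1.0
) -> tuple[float, float, float]:
    """Per-axis rate of prominent peaks in the joint-summed momentum trace.

    For each spatial axis the per-joint momenta are summed into one series;
    local maxima of its absolute value with prominence at least
    ``prominence`` times the series SD are counted and divided by the
    duration of the valid range.  A zero-variance series yields rate 0.
    """
    series = trace.L.sum(axis=1)  # (N', 3)
    if series.shape[0] < 3:
        return (0.0, 0.0, 0.0)
    duration = series.shape[0] / fps
    rates = []
    for axis in range(3):
        s = series[:, axis]
        sd = np.std(s)
        if sd == 0:
            rates.append(0.0)
            continue
        peaks, _ = find_peaks(np.abs(s), prominence=prominence * sd)
        rates.append(len(peaks) / duration)
    return tuple(rates)  # type: ignore[return-value]


def expandedness_stats(pose: PoseSequence, sacrum: SacrumTrack) -> tuple[float, float]:
    """Mean and SD of joint-to-sacrum distance over joints and frames (m)."""
    D = np.linalg.norm(pose.positions - sacrum.positions[:, None, :], axis=-1)
    return float(D.mean()), _pop_sd(D)


def sacrum_translation_stats(
    sacrum: SacrumTrack, sacrum_velocity: np.ndarray, vertical_axis: int = 1
) -> tuple[float, float]:
    """Mean planar sacrum speed (m/s) and SD of sacrum height (m)."""
    horiz = [a for a in (0, 1, 2) if a != vertical_axis]
    xz_speed = float(np.linalg.norm(sacrum_velocity[..., horiz], axis=-1).mean())
    height_sd = _pop_sd(sacrum.positions[:, vertical_axis])
    return xz_speed, height_sd


def _normalized_autocorr(s: np.ndarray, biased: bool = False) -> np.ndarray:
    """Variance-normalized autocorrelation at lags 1..N//2.

    The unbiased estimator (divide by N - lag) keeps a periodic signal's
    peaks near 1 at every lag; the biased one (divide by N) tapers with
    lag but has uniformly bounded variance under white noise, which is
    what a significance band needs.
    """
    s = s - s.mean()
    n = len(s)
    var = np.dot(s, s) / n
    max_lag = n // 2
    full = np.correlate(s, s, mode="full")[n - 1 :]  # lag 0..n-1 sums
    lags = np.arange(max_lag + 1)
    denom = np.full(max_lag + 1, float(n)) if biased else (n - lags).astype(float)
    r = full[: max_lag + 1] / denom / var
    return r[1:]


def bounce_features(sacrum: SacrumTrack, fps: float, vertical_axis: int = 1) -> tuple[float, float]:
    """Dominant vertical-oscillation frequency (Hz) and its regularity in [0, 1].

    Frequency is the arg-max of the magnitude spectrum of the mean-removed
    vertical sacrum series (zero bin excluded).  Regularity is the height
    of the first prominent peak of the unbiased normalized autocorrelation
    at positive lags, clipped to [0, 1]; a constant series returns (0, 0)
    and aperiodic noise gives regularity near 0.
    """
    s = sacrum.positions[:, vertical_axis]
    n = len(s)
    if n < 2 * fps:
        raise LengthError("bounce features need at least 2 s of frames")
    s = s - s.mean()
    if np.std(s) == 0:
        return 0.0, 0.0
    spectrum = np.abs(np.fft.rfft(s))
    k = int(np.argmax(spectrum[1:])) + 1
    frequency = k * fps / n
    r = _normalized_autocorr(s)
    peaks, props = find_peaks(r, prominence=0.05)
    regularity = float(np.clip(r[peaks[0]], 0.0, 1.0)) if len(peaks) else 0.0
    return float(frequency), regularity


def autocorr_peak_counts(
    trace: AngularMomentumTrace, fps: float, prominence: float = 1.0
) -> tuple[int, int, int]:
    """Per-axis counts of prominent peaks in the momentum autocorrelation.

    A rhythmically uniform dance repeats similar angular-momentum values at
    regular intervals, producing autocorrelation peaks at multiples of the
    beat period.  Peaks over lags up to half the sequence are counted when
    their prominence is at least ``prominence`` times the autocorrelation's
    SD *and* their height clears the white-noise significance band
    (3/sqrt(N)), so aperiodic sequences count near zero.
    """
    series = trace.L.sum(axis=1)
    n = series.shape[0]
    if n < 4 * fps:
        raise LengthError("autocorrelation peak counts need at least 4 s of frames")
    counts = []
    for axis in range(3):
        s = series[:, axis]
        if np.std(s) == 0:
            counts.append(0)
            continue
        r = _normalized_autocorr(s, biased=True)
        sd = np.std(r)
        band = 3.0 / math.sqrt(n)  # white-noise 99.7% significance band
        peaks, _ = find_peaks(r, prominence=prominence * sd, height=band)
        counts.append(int(len(peaks)))
    return tuple(counts)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def extract_features(
    pose: PoseSequence,
    registry: FeatureRegistry | None = None,
    smoothing: SmoothingConfig | None = None,
    prominence: float = 1.0,
    literal_xz_rotation: bool = False,
) -> FeatureVector:
    """Compute the full feature vector for one pose sequence.

    Runs sacrum estimation and differentiation once, then every registry
    computation; failures are re-raised naming the offending feature.
    """
    registry = registry or default_registry()
    smoothing = smoothing or SmoothingConfig()
    v_axis = pose.layout.vertical_axis

    sacrum = estimate_sacrum(pose)
    stack = differentiate(pose.positions, pose.fps, smoothing)
    sacrum_stack = differentiate(sacrum.positions, pose.fps, smoothing)
    sacrum_vel = sacrum_stack.velocity[:, 0, :]
    sacrum_jerk = sacrum_stack.jerk[:, 0, :]
    trace = angular_momentum_trace(pose, sacrum, stack)

    values: dict[str, float] = {}

    def compute(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise FeatureError(f"feature {name!r} failed: {exc}") from exc

    xz_speed, height_sd = compute(
        "sacrum_xz_speed_mean", lambda: sacrum_translation_stats(sacrum, sacrum_vel, v_axis)
    )
    bounce_f, bounce_r = compute("bounce_frequency", lambda: bounce_features(sacrum, pose.fps, v_axis))
    mean_mag, sd_mag, rotation = compute(
        "angmom_mean_mag",
        lambda: angular_momentum_stats(trace, v_axis, literal_xz=literal_xz_rotation),
    )
    rate_x, rate_y, rate_z = compute(
        "sharp_rate_x", lambda: sharp_movement_counts(trace, pose.fps, prominence)
    )
    exp_mean, exp_sd = compute("expandedness_mean", lambda: expandedness_stats(pose, sacrum))
    ah_mean, ah_sd = compute("ankle_height_mean", lambda: ankle_height_stats(pose))

    values["sacrum_xz_speed_mean"] = xz_speed
    values["sacrum_height_sd"] = height_sd
    values["sacrum_jerkiness"] = compute("sacrum_jerkiness", lambda: sacrum_jerkiness(sacrum_jerk))
    values["bounce_frequency"] = bounce_f
    values["bounce_regularity"] = bounce_r
    values["wrist_accel_mean"] = compute(
        "wrist_accel_mean", lambda: extremity_acceleration(stack, pose, "wrists")
    )
    values["ankle_accel_mean"] = compute(
        "ankle_accel_mean", lambda: extremity_acceleration(stack, pose, "ankles")
    )
    values["ankle_height_mean"] = ah_mean
    values["ankle_height_sd"] = ah_sd
    values["angmom_mean_mag"] = mean_mag
    values["angmom_sd_mag"] = sd_mag
    values["horizontal_rotation"] = rotation
    values["sharp_rate_x"] = rate_x
    values["sharp_rate_y"] = rate_y
    values["sharp_rate_z"] = rate_z
    values["expandedness_mean"] = exp_mean
    values["expandedness_sd"] = exp_sd

    if registry.augmented:
        n_x, n_y, n_z = compute(
            "autocorr_peak_rate_x", lambda: autocorr_peak_counts(trace, pose.fps, prominence)
        )
        duration = trace.n_frames / pose.fps
        values["autocorr_peak_rate_x"] = n_x / duration
        values["autocorr_peak_rate_y"] = n_y / duration
        values["autocorr_peak_rate_z"] = n_z / duration

    ordered = {name: values[name] for name in registry.names}
    return FeatureVector(
        values=ordered, sequence_id=pose.sequence_id, genre=pose.genre, tier=pose.tier
    )


def extract_feature_matrix(
    dataset,
    registry: FeatureRegistry | None = None,
    smoothing: SmoothingConfig | None = None,
    **kwargs,
) -> FeatureMatrix:
    """Extract features for every sequence of a dataset."""
    registry = registry or default_registry()
    rows = [extract_features(seq, registry, smoothing, **kwargs) for seq in dataset.sequences]
    return FeatureMatrix(rows=rows, registry=registry)
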