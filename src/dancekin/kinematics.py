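"""Sacrum estimation and smoothed finite-difference derivatives.

The COCO skeleton has no sacrum keypoint, so the sacrum is approximated as
the midpoint of the two hip joints.  Velocity, acceleration and jerk are
forward finite differences of position, with an optional Savitzky-Golay
least-squares smoothing pass applied after each differencing stage to keep
sensor noise from being amplified by repeated differentiation.  All three
derivative arrays are trimmed to the common valid range ``N' = N - 3`` so
downstream features average over an identical set of frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, LayoutError, LengthError
from .pose_io import PoseSequence

__all__ = ["SmoothingConfig", "SacrumTrack", "DerivativeStack", "estimate_sacrum", "smooth", "differentiate"]


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky-Golay smoothing parameters.

    The default window of 31 frames (~0.52 s at 60 fps) with a cubic local
    polynomial suppresses per-frame keypoint jitter while preserving motion
    at dance-movement timescales (a few Hz and below).
    """

    enabled: bool = True
    window: int = 31
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ConfigError(f"window must be an odd integer >= 5, got {self.window}")
        if not 2 <= self.polyorder < self.window:
            raise ConfigError(
                f"polyorder must satisfy 2 <= polyorder < window, got {self.polyorder}"
            )


@dataclass
class SacrumTrack:
    """Per-frame sacrum position estimate, ``(N, 3)`` meters."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"sacrum track must be (N, 3), got {self.positions.shape}")


@dataclass
class DerivativeStack:
    """Smoothed velocity, acceleration and jerk over the common valid range.

    All arrays are ``(N', J, 3)`` with ``N' = N - 3``; units m/s, m/s^2, m/s^3.
    """

    velocity: np.ndarray
    acceleration: np.ndarray
    jerk: np.ndarray
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)

    def __post_init__(self) -> None:
        shapes = {self.velocity.shape, self.acceleration.shape, self.jerk.shape}
        if len(shapes) != 1:
            raise ValueError(f"derivative arrays must share a shape, got {shapes}")

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]


def estimate_sacrum(pose: PoseSequence) -> SacrumTrack:
    """Midpoint of the left and right hip at every frame."""
    roles = pose.layout.role_index
    try:
        lh, rh = roles["left_hip"], roles["right_hip"]
    except KeyError as exc:  # pragma: no cover - layout validates at build time
        raise LayoutError("layout must define both hip roles") from exc
    return SacrumTrack(0.5 * (pose.positions[:, lh, :] + pose.positions[:, rh, :]))


def smooth(series: np.ndarray, config: SmoothingConfig) -> np.ndarray:
    """Savitzky-Golay smooth a series along its first (time) axis.

    Identity when smoothing is disabled.  Edges are handled by polynomial
    interpolation so the output length equals the input length.
    """
    series = np.asarray(series, dtype=float)
    if not config.enabled:
        return series
    if series.shape[0] < config.window:
        raise LengthError(
            f"series of length {series.shape[0]} is shorter than window {config.window}"
        )
    return savgol_filter(series, config.window, config.polyorder, axis=0, mode="interp")


def differentiate(
    positions: np.ndarray, fps: float, config: SmoothingConfig | None = None
) -> DerivativeStack:
    """First three forward-difference derivatives of joint positions.

    ``positions`` is ``(N, J, 3)`` (or ``(N, 3)``, treated as one joint).
    Each derivative is the forward difference of the previous (smoothed)
    stage divided by the frame interval; all outputs are trimmed to the
    first ``N - 3`` frames.
    """
    config = config or SmoothingConfig()
    positions = np.asarray(positions, dtype=float)
    squeeze = positions.ndim == 2
    if squeeze:
        positions = positions[:, None, :]
    n = positions.shape[0]
    if n < 4:
        raise LengthError("differentiation needs at least 4 frames")
    if config.enabled and n - 3 < config.window:
        raise LengthError(
            f"{n} frames is too short for smoothing window {config.window} "
            "(need N >= window + 3)"
        )
    dt = 1.0 / fps
    vel = smooth(np.diff(positions, axis=0) / dt, config)          # N-1
    acc = smooth(np.diff(vel, axis=0) / dt, config)                # N-2
    jerk = smooth(np.diff(acc, axis=0) / dt, config)               # N-3
    n_valid = n - 3
    out = DerivativeStack(
        velocity=vel[:n_valid], acceleration=acc[:n_valid], jerk=jerk[:n_valid], smoothing=config
    )
    if squeeze:
        pass  # arrays keep the (N', 1, 3) shape; callers index joint 0
    return out
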