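"""Reading, writing and splitting 3D pose sequences.

A pose sequence is an ``(N, J, 3)`` array of joint positions sampled at a
fixed frame rate, together with a skeleton layout that names the joints and
maps the six roles the feature pipeline needs (hips, wrists, ankles) to
joint indices.  The default layout is the 17-keypoint COCO skeleton used by
the AIST++ dance dataset; Y (axis 1) is up by convention, and coordinates
are treated as meters.

Supported on-disk dialects:

* ``aist_keypoints`` — a pickled mapping holding an ``(N, 17, 3)`` array
  under the key ``"keypoints3d"`` (the container format AIST++ ships);
* ``json`` — ``{"sequence_id", "fps", "joints": [...], "frames": [[...]]}``;
* ``csv`` — long table with columns ``frame, joint, x, y, z``.
"""

from __future__ import annotations

import json
import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, LabelError, LayoutError, LengthError, SplitError

__all__ = [
    "JointLayout",
    "PoseSequence",
    "Dataset",
    "COCO17",
    "GENRES",
    "AistNaming",
    "DEFAULT_AIST_NAMING",
    "read_pose_sequence",
    "write_pose_json",
    "write_pose_csv",
    "parse_aist_name",
    "split_advanced_test",
    "write_feature_table",
    "read_feature_table",
]

#: The ten-genre vocabulary, alphabetical.
GENRES: tuple[str, ...] = (
    "Ballet Jazz",
    "Break",
    "House",
    "Krump",
    "LA Hip Hop",
    "Lock",
    "Middle Hip Hop",
    "Pop",
    "Street Jazz",
    "Waack",
)

ROLES = ("left_hip", "right_hip", "left_wrist", "right_wrist", "left_ankle", "right_ankle")


@dataclass(frozen=True)
class JointLayout:
    """Names and role indices of a skeleton.

    Parameters
    ----------
    joint_names
        Ordered joint names; the position array's joint axis follows this order.
    role_index
        Maps each of the six required roles (``left_hip``, ``right_hip``,
        ``left_wrist``, ``right_wrist``, ``left_ankle``, ``right_ankle``)
        to a joint index.
    vertical_axis
        Which coordinate axis points up. Default 1 (Y-up).
    """

    joint_names: tuple[str, ...]
    role_index: Mapping[str, int]
    vertical_axis: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "joint_names", tuple(self.joint_names))
        object.__setattr__(self, "role_index", dict(self.role_index))
        missing = [r for r in ROLES if r not in self.role_index]
        if missing:
            raise LayoutError(f"layout is missing roles: {missing}")
        idx = [self.role_index[r] for r in ROLES]
        if len(set(idx)) != len(idx):
            raise LayoutError("role indices must be distinct")
        if any(i < 0 or i >= len(self.joint_names) for i in idx):
            raise LayoutError("role index out of range")
        if self.vertical_axis not in (0, 1, 2):
            raise LayoutError("vertical_axis must be 0, 1 or 2")

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    def horizontal_axes(self) -> tuple[int, int]:
        """The two axes spanning the floor plane, in ascending order."""
        return tuple(a for a in (0, 1, 2) if a != self.vertical_axis)  # type: ignore[return-value]


_COCO17_NAMES = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: The standard 17-keypoint COCO layout, Y-up.
COCO17 = JointLayout(
    joint_names=_COCO17_NAMES,
    role_index={
        "left_wrist": 9,
        "right_wrist": 10,
        "left_hip": 11,
        "right_hip": 12,
        "left_ankle": 15,
        "right_ankle": 16,
    },
)


@dataclass
class PoseSequence:
    """A fixed-skeleton 3D joint trajectory at a constant frame rate."""

    sequence_id: str
    fps: float
    positions: np.ndarray  # (N, J, 3), meters
    layout: JointLayout = COCO17
    genre: str | None = None
    tier: str | None = None  # "basic" | "advanced"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.fps <= 0:
            raise DataError(f"fps must be positive, got {self.fps}")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise DataError(f"positions must be (N, J, 3), got {self.positions.shape}")
        if self.positions.shape[0] < 4:
            raise LengthError("sequence needs at least 4 frames (third differences)")
        if self.positions.shape[1] != self.layout.n_joints:
            raise DataError(
                f"joint count {self.positions.shape[1]} does not match layout "
                f"({self.layout.n_joints})"
            )
        if not np.isfinite(self.positions).all():
            raise DataError("positions contain non-finite values")
        if self.tier not in (None, "basic", "advanced"):
            raise DataError(f"tier must be basic/advanced, got {self.tier!r}")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        """Sequence duration in seconds."""
        return self.n_frames / self.fps


@dataclass
class Dataset:
    """A collection of pose sequences with a shared genre vocabulary."""

    sequences: list[PoseSequence]
    genre_vocabulary: tuple[str, ...] = GENRES

    def __post_init__(self) -> None:
        self.genre_vocabulary = tuple(self.genre_vocabulary)
        vocab = set(self.genre_vocabulary)
        for seq in self.sequences:
            if seq.genre is not None and seq.genre not in vocab:
                raise LabelError(f"{seq.sequence_id}: genre {seq.genre!r} not in vocabulary")

    def __len__(self) -> int:
        return len(self.sequences)

    def by_tier(self, tier: str) -> list[PoseSequence]:
        return [s for s in self.sequences if s.tier == tier]


# ---------------------------------------------------------------------------
# AIST++ naming convention
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AistNaming:
    """Editable token tables for the AIST++ file-naming convention.

    AIST++ encodes the genre in a ``gXX`` token and the situation (basic
    vs. advanced dance) in a ``sXX`` token of the underscore-separated
    sequence id, e.g. ``gBR_sBM_cAll_d04_mBR0_ch01``.  The tables ship as
    data so they can be corrected without touching code.
    """

    genre_tokens: Mapping[str, str] = field(
        default_factory=lambda: {
            "gJB": "Ballet Jazz",
            "gBR": "Break",
            "gHO": "House",
            "gKR": "Krump",
            "gLH": "LA Hip Hop",
            "gLO": "Lock",
            "gMH": "Middle Hip Hop",
            "gPO": "Pop",
            "gJS": "Street Jazz",
            "gWA": "Waack",
        }
    )
    tier_tokens: Mapping[str, str] = field(
        default_factory=lambda: {"sBM": "basic", "sFM": "advanced"}
    )


DEFAULT_AIST_NAMING = AistNaming()


def parse_aist_name(
    sequence_id: str, naming: AistNaming = DEFAULT_AIST_NAMING
) -> tuple[str | None, str | None]:
    """Decode ``(genre, tier)`` from an AIST++-style sequence id.

    Pure function; unrecognized ids yield ``(None, None)``.
    """
    tokens = Path(sequence_id).stem.split("_")
    genre = next((naming.genre_tokens[t] for t in tokens if t in naming.genre_tokens), None)
    tier = next((naming.tier_tokens[t] for t in tokens if t in naming.tier_tokens), None)
    return genre, tier


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _interpolate_missing(positions: np.ndarray, fps: float) -> np.ndarray:
    """Linearly interpolate NaN runs per coordinate; abort on long gaps.

    Gaps longer than 0.5 s of consecutive all-NaN frames, and NaNs at the
    ends of the sequence, cannot be repaired and raise :class:`DataError`.
    """
    if np.isfinite(positions).all():
        return positions
    n = positions.shape[0]
    flat = positions.reshape(n, -1)
    max_gap = max(1, int(round(0.5 * fps)))
    bad_frame = ~np.isfinite(flat).all(axis=1)
    # length of each run of bad frames
    run = 0
    for i in range(n):
        run = run + 1 if bad_frame[i] else 0
        if run > max_gap:
            raise DataError(f"missing-data run exceeds 0.5 s ({max_gap} frames)")
    out = flat.copy()
    idx = np.arange(n)
    for c in range(flat.shape[1]):
        col = flat[:, c]
        good = np.isfinite(col)
        if good.all():
            continue
        if not good.any() or not (good[0] and good[-1]):
            raise DataError("cannot interpolate missing data at sequence boundaries")
        out[:, c] = np.interp(idx, idx[good], col[good])
    result = out.reshape(positions.shape)
    if not np.isfinite(result).all():
        raise DataError("non-finite values remain after interpolation")
    return result


def _z_up_to_y_up(positions: np.ndarray) -> np.ndarray:
    """Rotate a Z-up frame into the package's Y-up convention: (x,y,z) -> (x,z,-y)."""
    out = np.empty_like(positions)
    out[..., 0] = positions[..., 0]
    out[..., 1] = positions[..., 2]
    out[..., 2] = -positions[..., 1]
    return out


def read_pose_sequence(
    path: str | Path,
    format: str = "auto",
    layout: JointLayout = COCO17,
    fps: float = 60.0,
    naming: AistNaming = DEFAULT_AIST_NAMING,
    z_up: bool = False,
) -> PoseSequence:
    """Read one pose sequence from disk.

    ``format`` is one of ``aist_keypoints``, ``json``, ``csv`` or ``auto``
    (inferred from the file suffix).  The genre and tier are decoded from
    the file name when it follows the AIST++ convention.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if format == "auto":
        format = {".json": "json", ".csv": "csv", ".pkl": "aist_keypoints"}.get(
            path.suffix.lower(), "aist_keypoints"
        )

    if format == "aist_keypoints":
        with open(path, "rb") as fh:
            container = pickle.load(fh)
        if not isinstance(container, Mapping) or (
            "keypoints3d" not in container and "keypoints3d_optim" not in container
        ):
            raise DataError(f"{path}: not an AIST keypoint container")
        arr = np.asarray(
            container.get("keypoints3d", container.get("keypoints3d_optim")), dtype=float
        )
    elif format == "json":
        with open(path) as fh:
            doc = json.load(fh)
        arr = np.asarray(doc["frames"], dtype=float)
        fps = float(doc.get("fps", fps))
        if "joints" in doc and tuple(doc["joints"]) != layout.joint_names:
            raise LayoutError(f"{path}: joint names do not match layout")
    elif format == "csv":
        df = pd.read_csv(path, comment="#")
        required = {"frame", "joint", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise DataError(f"{path}: CSV must have columns {sorted(required)}")
        if df["joint"].dtype == object:
            name_to_idx = {n: i for i, n in enumerate(layout.joint_names)}
            try:
                df = df.assign(joint=df["joint"].map(name_to_idx).astype(int))
            except (ValueError, TypeError) as exc:
                raise LayoutError(f"{path}: unknown joint name") from exc
        n = int(df["frame"].max()) + 1
        arr = np.full((n, layout.n_joints, 3), np.nan)
        arr[df["frame"].to_numpy(int), df["joint"].to_numpy(int)] = df[["x", "y", "z"]].to_numpy(
            float
        )
    else:
        raise DataError(f"unknown format {format!r}")

    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DataError(f"{path}: expected (N, J, 3) positions, got {arr.shape}")
    if arr.shape[1] != layout.n_joints:
        raise LayoutError(
            f"{path}: {arr.shape[1]} joints per frame, layout has {layout.n_joints}"
        )
    if z_up:
        arr = _z_up_to_y_up(arr)
    arr = _interpolate_missing(arr, fps)
    if arr.shape[0] < 4:
        raise LengthError(f"{path}: fewer than 4 usable frames")
    seq_id = path.stem
    genre, tier = parse_aist_name(seq_id, naming)
    if format == "json":  # explicit labels in the file take precedence
        genre = doc.get("genre", genre)
        tier = doc.get("tier", tier)
    return PoseSequence(
        sequence_id=seq_id, fps=fps, positions=arr, layout=layout, genre=genre, tier=tier
    )


def write_pose_json(seq: PoseSequence, path: str | Path) -> None:
    """Write a sequence as JSON; floats round-trip exactly."""
    doc = {
        "sequence_id": seq.sequence_id,
        "fps": seq.fps,
        "joints": list(seq.layout.joint_names),
        "frames": seq.positions.tolist(),
    }
    if seq.genre is not None:
        doc["genre"] = seq.genre
    if seq.tier is not None:
        doc["tier"] = seq.tier
    Path(path).write_text(json.dumps(doc))


def write_pose_csv(seq: PoseSequence, path: str | Path) -> None:
    """Write a sequence as a long ``frame, joint, x, y, z`` CSV."""
    n, j, _ = seq.positions.shape
    frames = np.repeat(np.arange(n), j)
    joints = np.tile(np.arange(j), n)
    flat = seq.positions.reshape(-1, 3)
    df = pd.DataFrame(
        {"frame": frames, "joint": joints, "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_advanced_test(
    data: Dataset, advanced_test_fraction: float = 0.52, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Build an advanced-only test set.

    Per genre, a fraction of the advanced sequences (rounded half up) is
    sampled into the test set; all basic sequences and the remaining
    advanced sequences form the training set.  This mirrors a study design
    where short repetitive "basic" material trains a model evaluated on
    long, individualized "advanced" choreography.
    """
    if not 0 < advanced_test_fraction < 1:
        raise SplitError(f"fraction must be in (0, 1), got {advanced_test_fraction}")
    advanced = data.by_tier("advanced")
    if not advanced:
        raise SplitError("dataset has no advanced sequences to sample a test set from")
    rng = np.random.default_rng(seed)
    by_genre: dict[str | None, list[PoseSequence]] = {}
    for seq in advanced:
        by_genre.setdefault(seq.genre, []).append(seq)
    test_ids: set[str] = set()
    for genre in sorted(by_genre, key=lambda g: (g is None, g)):
        group = sorted(by_genre[genre], key=lambda s: s.sequence_id)
        k = min(len(group), _round_half_up(advanced_test_fraction * len(group)))
        chosen = rng.choice(len(group), size=k, replace=False)
        test_ids.update(group[i].sequence_id for i in chosen)
    train = [s for s in data.sequences if s.sequence_id not in test_ids]
    test = [s for s in data.sequences if s.sequence_id in test_ids]
    return (
        Dataset(train, data.genre_vocabulary),
        Dataset(test, data.genre_vocabulary),
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

_META_COLS = ["sequence_id", "genre", "tier"]


def write_feature_table(matrix, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
    """Write a feature matrix as CSV: id/label columns then features in registry order.

    ``metadata`` key/value pairs are embedded as ``#`` comment lines so a
    table records the configuration that produced it.
    """
    df = matrix.to_dataframe()
    if df.empty:
        raise DataError("feature matrix is empty")
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_feature_table(path: str | Path):
    """Read a feature table CSV back into a :class:`~dancekin.features.FeatureMatrix`."""
    from .features import FeatureMatrix, FeatureVector, registry_from_names

    df = pd.read_csv(path, comment="#")
    feature_names = [c for c in df.columns if c not in _META_COLS]
    registry = registry_from_names(feature_names)
    rows = []
    for _, row in df.iterrows():
        rows.append(
            FeatureVector(
                values={name: float(row[name]) for name in feature_names},
                sequence_id=str(row["sequence_id"]),
                genre=None if pd.isna(row["genre"]) else str(row["genre"]),
                tier=None if pd.isna(row["tier"]) else str(row["tier"]),
            )
        )
    return FeatureMatrix(rows=rows, registry=registry)
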