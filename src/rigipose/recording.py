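"""Motion recordings and keypoint preprocessing.

A :class:`MotionRecording` holds the raw per-frame keypoints of one subject
performing one source motion, in image-pixel convention (origin top-left,
y increasing downward), each joint an ``(x, y, confidence)`` triplet.
:func:`preprocess_recording` cleans it into a :class:`CleanRecording`:
low-confidence joints are treated as missing and gap-filled, coordinates are
divided by a body-size scale (median trunk length, or wrist-to-middle-knuckle
length for hand-only recordings) and the vertical axis is flipped so that
anatomical "up" is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, RejectionError, SchemaError
from .skeletons import BODY_25, HAND_21, MOTIONS, SkeletonDef

__all__ = [
    "MotionRecording",
    "CleanRecording",
    "PreprocessConfig",
    "preprocess_recording",
]


@dataclass
class MotionRecording:
    """One subject performing one motion, as keypoint (or AU) time series.

    Exactly one of two payload shapes is used: the facial-expression motion
    (``FE``) carries ``au`` (frames x 46 AU intensities); every other motion
    carries ``body`` and/or the two hand arrays, each of shape
    ``(n_frames, n_joints, 3)`` with columns x, y, confidence.
    """

    subject_id: str
    motion: str
    frame_rate: float
    skeleton: SkeletonDef
    body: np.ndarray | None = None
    left_hand: np.ndarray | None = None
    right_hand: np.ndarray | None = None
    au: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.motion not in MOTIONS:
            raise SchemaError(f"unknown motion {self.motion!r}")
        if self.frame_rate <= 0:
            raise SchemaError("frame_rate must be positive")
        if self.motion == "FE":
            if self.au is None:
                raise SchemaError("FE recordings must carry an AU table")
            if len(self.au) < 2:
                raise SchemaError("AU table needs at least 2 frames")
        else:
            if self.body is None and self.left_hand is None and self.right_hand is None:
                raise SchemaError(
                    f"{self.motion} recording carries no keypoint arrays"
                )
            n = self.n_frames
            for name, arr, expected in (
                ("body", self.body, BODY_25.n_joints),
                ("left_hand", self.left_hand, HAND_21.n_joints),
                ("right_hand", self.right_hand, HAND_21.n_joints),
            ):
                if arr is None:
                    continue
                arr = np.asarray(arr, dtype=float)
                if arr.ndim != 3 or arr.shape[1] != expected or arr.shape[2] != 3:
                    raise SchemaError(
                        f"{name} array must have shape (n_frames, {expected}, 3), "
                        f"got {arr.shape}"
                    )
                if arr.shape[0] != n:
                    raise SchemaError("keypoint arrays disagree on frame count")
                conf = arr[:, :, 2]
                if np.nanmin(conf) < 0 or np.nanmax(conf) > 1:
                    raise SchemaError("confidences must lie in [0, 1]")
            if n < 2:
                raise SchemaError("recording needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        for arr in (self.body, self.left_hand, self.right_hand):
            if arr is not None:
                return int(np.asarray(arr).shape[0])
        return len(self.au) if self.au is not None else 0

    def arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, arr in (
            ("body", self.body),
            ("left_hand", self.left_hand),
            ("right_hand", self.right_hand),
        ):
            if arr is not None:
                out[name] = np.asarray(arr, dtype=float)
        return out


@dataclass
class PreprocessConfig:
    """Keypoint cleaning settings.

    confidence_threshold : joints below it are treated as missing.
    max_gap : longest interior missing run (frames) filled by linear
        interpolation; longer runs are held at the nearest valid sample.
    max_missing : a required joint missing in more than this fraction of
        frames rejects the recording.
    required_joints : joints quality-controlled against ``max_missing``;
        ``None`` checks every joint that is not missing in all frames.
    """

    confidence_threshold: float = 0.3
    max_gap: int = 5
    max_missing: float = 0.3
    required_joints: tuple[str, ...] | None = None


@dataclass
class CleanRecording:
    """A preprocessed recording: normalized, y-up, gap-free coordinates.

    ``coords`` maps array name (body / left_hand / right_hand) to an
    ``(n_frames, n_joints, 2)`` array in body-size units with anatomical
    "up" positive. ``scale`` is the pixel length used for normalization.
    """

    subject_id: str
    motion: str
    frame_rate: float
    skeleton: SkeletonDef
    coords: dict[str, np.ndarray] = field(default_factory=dict)
    au: pd.DataFrame | None = None
    scale: float = 1.0
    missingness: dict[str, np.ndarray] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        for arr in self.coords.values():
            return int(arr.shape[0])
        return len(self.au) if self.au is not None else 0

    def joint_xy(self, array: str, joint: str) -> np.ndarray:
        """Per-frame (x, y-up) normalized coordinates of one joint."""
        skel = BODY_25 if array == "body" else HAND_21
        return self.coords[array][:, skel.index(joint), :]

    def as_recording(self) -> MotionRecording:
        """Re-express as a raw-convention recording (y-down, confidence 1).

        Feeding the result back through :func:`preprocess_recording` is the
        identity on gap-free inputs (the trunk scale is already 1).
        """
        arrays: dict[str, np.ndarray] = {}
        for name, xy in self.coords.items():
            arr = np.empty((xy.shape[0], xy.shape[1], 3))
            arr[:, :, 0] = xy[:, :, 0]
            arr[:, :, 1] = -xy[:, :, 1]
            arr[:, :, 2] = 1.0
            arrays[name] = arr
        return MotionRecording(
            subject_id=self.subject_id,
            motion=self.motion,
            frame_rate=self.frame_rate,
            skeleton=self.skeleton,
            body=arrays.get("body"),
            left_hand=arrays.get("left_hand"),
            right_hand=arrays.get("right_hand"),
            au=None if self.au is None else self.au.copy(),
        )


def _fill_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill NaN runs in a 1-D series.

    Interior runs of length <= max_gap are linearly interpolated; longer
    interior runs and edge runs are held at the nearest valid sample.
    """
    v = values.copy()
    isnan = np.isnan(v)
    if not isnan.any():
        return v
    idx = np.arange(v.size)
    valid = ~isnan
    if valid.sum() == 0:
        return v
    # Locate runs of NaN.
    run_starts = np.flatnonzero(isnan & ~np.r_[False, isnan[:-1]])
    run_ends = np.flatnonzero(isnan & ~np.r_[isnan[1:], False])
    interp = np.interp(idx, idx[valid], v[valid])
    for s, e in zip(run_starts, run_ends):
        length = e - s + 1
        interior = s > 0 and e < v.size - 1
        if interior and length <= max_gap:
            v[s : e + 1] = interp[s : e + 1]
        else:
            # Hold nearest valid sample (edges collapse to one side).
            left = s - 1 if s > 0 else None
            right = e + 1 if e < v.size - 1 else None
            if left is not None and right is not None:
                mid = (s + e) // 2
                v[s : mid + 1] = v[left]
                v[mid + 1 : e + 1] = v[right]
            elif left is not None:
                v[s : e + 1] = v[left]
            else:
                v[s : e + 1] = v[right]
    return v


def _median_segment_length(
    arr: np.ndarray, i: int, j: int
) -> float:
    """Median Euclidean distance between joints i and j over valid frames."""
    d = np.linalg.norm(arr[:, i, :2] - arr[:, j, :2], axis=1)
    d = d[~np.isnan(d)]
    return float(np.median(d)) if d.size else np.nan


def preprocess_recording(
    rec: MotionRecording, config: PreprocessConfig | None = None
) -> CleanRecording:
    """Clean and normalize a raw recording.

    Keypoints with confidence below the threshold become missing and are
    gap-filled per joint and coordinate. Coordinates are divided by the
    median trunk length (Neck-MidHip; wrist to middle knuckle when only
    hands are present) and the vertical axis is flipped to anatomical y-up.

    Raises
    ------
    RejectionError
        if a required joint is missing in more than ``max_missing`` of
        frames.
    DegenerateGeometryError
        if the normalization segment has zero length.
    """
    config = config or PreprocessConfig()
    log: list[str] = []

    if rec.motion == "FE":
        return CleanRecording(
            subject_id=rec.subject_id,
            motion=rec.motion,
            frame_rate=rec.frame_rate,
            skeleton=rec.skeleton,
            au=rec.au.copy(),
            scale=1.0,
            log=["FE recording: AU intensities passed through"],
        )

    arrays = rec.arrays()
    masked: dict[str, np.ndarray] = {}
    missingness: dict[str, np.ndarray] = {}
    for name, arr in arrays.items():
        xy = arr[:, :, :2].astype(float).copy()
        missing = arr[:, :, 2] < config.confidence_threshold
        xy[missing] = np.nan
        masked[name] = xy
        missingness[name] = missing.mean(axis=0)
        skel = BODY_25 if name == "body" else HAND_21
        required = config.required_joints
        for j, frac in enumerate(missingness[name]):
            joint = skel.joint_names[j]
            if required is not None and joint not in required:
                continue
            if required is None and frac >= 1.0:
                # Entirely absent optional joint: tolerated, held as NaN->0.
                log.append(f"{name}:{joint} absent in all frames")
                continue
            if frac > config.max_missing:
                raise RejectionError(
                    f"joint {joint!r} ({name}) missing in {frac:.0%} of frames "
                    f"(max allowed {config.max_missing:.0%})"
                )

    # Gap-fill per joint and coordinate.
    for name, xy in masked.items():
        for j in range(xy.shape[1]):
            for c in range(2):
                col = xy[:, j, c]
                if np.isnan(col).all():
                    xy[:, j, c] = 0.0
                    continue
                xy[:, j, c] = _fill_gaps(col, config.max_gap)
        n_filled = int(np.sum(missingness[name] > 0))
        if n_filled:
            log.append(f"{name}: gap-filled {n_filled} joints")

    # Normalization scale.
    if "body" in masked:
        scale = _median_segment_length(
            masked["body"], BODY_25.index("Neck"), BODY_25.index("MidHip")
        )
        seg = "Neck-MidHip"
    else:
        hand = masked.get("left_hand", masked.get("right_hand"))
        scale = _median_segment_length(
            hand, HAND_21.index("Wrist"), HAND_21.index("Middle1")
        )
        seg = "Wrist-Middle1"
    if not np.isfinite(scale) or scale <= 0:
        raise DegenerateGeometryError(
            f"normalization segment {seg} has zero or undefined length"
        )
    log.append(f"normalized by median {seg} length {scale:.6g} px")

    coords: dict[str, np.ndarray] = {}
    for name, xy in masked.items():
        out = np.empty_like(xy)
        out[:, :, 0] = xy[:, :, 0] / scale
        out[:, :, 1] = -xy[:, :, 1] / scale  # flip: anatomical up positive
        coords[name] = out

    return CleanRecording(
        subject_id=rec.subject_id,
        motion=rec.motion,
        frame_rate=rec.frame_rate,
        skeleton=rec.skeleton,
        coords=coords,
        scale=scale,
        missingness=missingness,
        log=log,
    )
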