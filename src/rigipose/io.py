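"""Reading and writing OpenPose-style keypoint files and AU tables.

Two on-disk layouts are accepted for keypoints: a directory of one JSON file
per frame (files sorted by name, i.e. by frame index) or a single JSON file
holding the list of frame records. Each frame record follows the OpenPose
output dialect::

    {"version": 1.3,
     "people": [{"pose_keypoints_2d": [x0, y0, c0, x1, y1, c1, ...],
                 "hand_left_keypoints_2d": [...],
                 "hand_right_keypoints_2d": [...]}]}

Frames with an empty ``people`` list are retained with every confidence set
to zero. When several people are detected, the person with the largest mean
bounding-box area is kept. AU intensity tables are CSV files with one row
per frame and one ``AU01``..``AU46`` column per action unit.

The writers exist so synthetic recordings round-trip through the exact
dialect a real deployment would produce.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .recording import MotionRecording
from .skeletons import BODY_25, FACE_AU, HAND_21, SkeletonDef

__all__ = [
    "read_openpose_frames",
    "write_openpose_frames",
    "read_face_aus",
    "write_face_aus",
]

_FIELDS = {
    "body": ("pose_keypoints_2d", BODY_25.n_joints),
    "left_hand": ("hand_left_keypoints_2d", HAND_21.n_joints),
    "right_hand": ("hand_right_keypoints_2d", HAND_21.n_joints),
}


def _person_area(person: dict) -> float:
    """Mean bounding-box area over the person's valid keypoints."""
    areas = []
    for key, _ in _FIELDS.values():
        flat = np.asarray(person.get(key, []), dtype=float)
        if flat.size == 0:
            continue
        pts = flat.reshape(-1, 3)
        ok = pts[:, 2] > 0
        if ok.sum() < 2:
            continue
        w = pts[ok, 0].max() - pts[ok, 0].min()
        h = pts[ok, 1].max() - pts[ok, 1].min()
        areas.append(w * h)
    return float(np.mean(areas)) if areas else 0.0


def _parse_frame(record: dict, where: str) -> dict[str, np.ndarray]:
    """Parse one frame record into {array name: (n_joints, 3)} blocks."""
    if not isinstance(record, dict) or "people" not in record:
        raise ParseError(f"{where}: frame record has no 'people' field")
    people = record["people"]
    if not isinstance(people, list):
        raise ParseError(f"{where}: 'people' is not a list")
    out: dict[str, np.ndarray] = {}
    if not people:
        return out
    person = max(people, key=_person_area)
    for name, (key, n_joints) in _FIELDS.items():
        flat = person.get(key)
        if flat is None or len(flat) == 0:
            continue
        arr = np.asarray(flat, dtype=float)
        if arr.size != n_joints * 3:
            raise SchemaError(
                f"{where}: {key} has {arr.size} values, expected {n_joints * 3}"
            )
        out[name] = arr.reshape(n_joints, 3)
    return out


def read_openpose_frames(
    path: str | Path,
    skeleton: SkeletonDef = BODY_25,
    motion: str = "GAIT",
    frame_rate: float = 20.0,
    subject_id: str = "unknown",
) -> MotionRecording:
    """Read a keypoint recording from per-frame JSONs or one concatenated file.

    Parameters
    ----------
    path : path
        Directory of per-frame ``*.json`` files (lexicographic order = frame
        order) or a single JSON file containing a list of frame records.
    skeleton : SkeletonDef
        Body layout the pose keypoints follow (``BODY_25``).
    motion, frame_rate, subject_id
        Recording metadata.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such path: {path}")
    if path.is_dir():
        files = sorted(path.glob("*.json"))
        if not files:
            raise ParseError(f"no frame JSONs in {path}")
        records = []
        names = []
        for f in files:
            try:
                records.append(json.loads(f.read_text()))
            except json.JSONDecodeError as exc:
                raise ParseError(f"{f}: invalid JSON ({exc})") from exc
            names.append(str(f))
    else:
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(payload, list):
            raise ParseError(f"{path}: concatenated file must hold a list")
        records = payload
        names = [f"{path}[{i}]" for i in range(len(records))]

    frames = []
    for i, (rec, name) in enumerate(zip(records, names)):
        try:
            frames.append(_parse_frame(rec, f"{name} (frame {i})"))
        except (ParseError, SchemaError):
            raise
        except Exception as exc:  # malformed in an unanticipated way
            raise ParseError(f"{name} (frame {i}): {exc}") from exc

    # Which arrays does this recording carry? Union over frames.
    present = sorted({k for fr in frames for k in fr})
    if not present:
        # Nobody ever detected: emit all-zero body frames.
        present = ["body"]
    arrays: dict[str, np.ndarray] = {}
    for name in present:
        n_joints = _FIELDS[name][1]
        stack = np.zeros((len(frames), n_joints, 3))
        for i, fr in enumerate(frames):
            if name in fr:
                stack[i] = fr[name]
            # absent detection: all confidences stay 0
        arrays[name] = stack

    return MotionRecording(
        subject_id=subject_id,
        motion=motion,
        frame_rate=frame_rate,
        skeleton=skeleton,
        body=arrays.get("body"),
        left_hand=arrays.get("left_hand"),
        right_hand=arrays.get("right_hand"),
    )


def write_openpose_frames(
    rec: MotionRecording,
    path: str | Path,
    per_frame: bool = True,
) -> None:
    """Write a recording in the OpenPose JSON dialect (fixture writer)."""
    path = Path(path)
    arrays = rec.arrays()
    records = []
    for i in range(rec.n_frames):
        person: dict[str, list[float]] = {"person_id": [-1]}
        for name, (key, _) in _FIELDS.items():
            if name in arrays:
                person[key] = [round(float(v), 6) for v in arrays[name][i].ravel()]
        records.append({"version": 1.3, "people": [person]})
    if per_frame:
        path.mkdir(parents=True, exist_ok=True)
        for i, record in enumerate(records):
            (path / f"{rec.subject_id}_{rec.motion}_{i:06d}_keypoints.json").write_text(
                json.dumps(record)
            )
    else:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(records))


def read_face_aus(
    path: str | Path,
    subject_id: str = "unknown",
    frame_rate: float = 20.0,
) -> MotionRecording:
    """Read a facial action-unit intensity table into an FE recording.

    The CSV must carry one column per AU (``AU01``..``AU46``) and one row
    per frame.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such path: {path}")
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read AU table ({exc})") from exc
    expected = list(FACE_AU.joint_names)
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise SchemaError(
            f"{path}: AU table missing columns {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    au = table[expected].astype(float).reset_index(drop=True)
    return MotionRecording(
        subject_id=subject_id,
        motion="FE",
        frame_rate=frame_rate,
        skeleton=FACE_AU,
        au=au,
    )


def write_face_aus(rec: MotionRecording, path: str | Path) -> None:
    """Write an FE recording's AU table as CSV (fixture writer)."""
    if rec.au is None:
        raise SchemaError("recording has no AU table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rec.au.to_csv(path, index=False, float_format="%.6f")
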