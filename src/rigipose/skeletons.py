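"""Keypoint skeleton layouts.

The package consumes OpenPose-style 2-D pose output: a 25-joint whole-body
layout (``BODY_25``), a 21-joint hand layout (``HAND_21``) and, for the
facial-expression item, a bank of 46 facial action-unit (AU) intensity
channels (``FACE_AU``). Pose estimation itself is out of scope; these
definitions only describe the layouts the reader expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SkeletonDef:
    """An ordered joint layout plus its left/right joint pairing.

    Parameters
    ----------
    name : str
        Layout identifier (``BODY_25``, ``HAND_21`` or ``FACE_AU``).
    joint_names : tuple of str
        Joint identifiers in keypoint order.
    sided_pairs : dict
        Map from each left-side joint name to its right-side counterpart.
    """

    name: str
    joint_names: tuple[str, ...]
    sided_pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.joint_names)) != len(self.joint_names):
            raise ValueError("duplicate joint names in skeleton %r" % self.name)
        for left, right in self.sided_pairs.items():
            if left == right:
                raise ValueError(f"sided pair maps {left!r} to itself")
            for j in (left, right):
                if j not in self.joint_names:
                    raise ValueError(f"sided pair references unknown joint {j!r}")

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    def index(self, joint: str) -> int:
        try:
            return self.joint_names.index(joint)
        except ValueError:
            raise KeyError(
                f"unknown joint {joint!r} in skeleton {self.name!r}"
            ) from None


# OpenPose BODY_25 order.
BODY_25 = SkeletonDef(
    name="BODY_25",
    joint_names=(
        "Nose", "Neck",
        "RShoulder", "RElbow", "RWrist",
        "LShoulder", "LElbow", "LWrist",
        "MidHip",
        "RHip", "RKnee", "RAnkle",
        "LHip", "LKnee", "LAnkle",
        "REye", "LEye", "REar", "LEar",
        "LBigToe", "LSmallToe", "LHeel",
        "RBigToe", "RSmallToe", "RHeel",
    ),
    sided_pairs={
        "LShoulder": "RShoulder",
        "LElbow": "RElbow",
        "LWrist": "RWrist",
        "LHip": "RHip",
        "LKnee": "RKnee",
        "LAnkle": "RAnkle",
        "LEye": "REye",
        "LEar": "REar",
        "LBigToe": "RBigToe",
        "LSmallToe": "RSmallToe",
        "LHeel": "RHeel",
    },
)

# OpenPose hand model: wrist + 4 joints per digit.
HAND_21 = SkeletonDef(
    name="HAND_21",
    joint_names=(
        "Wrist",
        "Thumb1", "Thumb2", "Thumb3", "Thumb4",
        "Index1", "Index2", "Index3", "Index4",
        "Middle1", "Middle2", "Middle3", "Middle4",
        "Ring1", "Ring2", "Ring3", "Ring4",
        "Pinky1", "Pinky2", "Pinky3", "Pinky4",
    ),
)

# Facial action-unit intensity channels (facial action coding system).
FACE_AU = SkeletonDef(
    name="FACE_AU",
    joint_names=tuple(f"AU{i:02d}" for i in range(1, 47)),
)

assert BODY_25.n_joints == 25
assert HAND_21.n_joints == 21
assert FACE_AU.n_joints == 46

# The 11 remotely performable source motions.
MOTIONS = (
    "FE",    # facial expression
    "FT",    # finger tapping
    "HM",    # hand movements (open/close)
    "PSOH",  # pronation-supination of the hands
    "TT",    # toe tapping
    "LA",    # leg agility
    "AFC",   # arising from chair
    "GAIT",  # walking
    "POS",   # quiet standing posture
    "PTOH",  # postural tremor of the hands
    "KTOH",  # kinetic tremor of the hands
)

# Motions whose signals live on the 21-joint hand layout.
HAND_MOTIONS = frozenset({"FT", "HM", "PSOH", "PTOH", "KTOH"})
# Voluntary cyclic motions (cycle kinematics are meaningful).
CYCLIC_MOTIONS = frozenset({"FT", "HM", "PSOH", "TT", "LA"})

# The four target items scored indirectly.
TARGETS = ("Rig-UE", "Rig-LE", "Rig-Neck", "PS")

# Default motion set feeding each target's model.
TARGET_MOTIONS: dict[str, tuple[str, ...]] = {
    "Rig-UE": ("FT", "HM", "PSOH", "AFC", "PTOH", "KTOH", "GAIT"),
    "Rig-LE": ("LA", "AFC", "GAIT", "TT"),
    "PS": ("LA", "AFC", "GAIT", "TT", "POS"),
    "Rig-Neck": MOTIONS,
}
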