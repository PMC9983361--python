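"""Per-motion signal channel map.

The scoring pipeline derives a small set of scalar channels from each source
motion, chosen to cover the joints that passive rigidity testing manipulates
(wrist, elbow, hip, knee, neck) and the sway axes relevant to postural
stability:

* FT — thumb-tip to index-tip distance per hand (tap aperture)
* HM — mean fingertip-to-wrist aperture per hand (open/close)
* PSOH — image-plane orientation of the knuckle line per hand
* TT — big-toe height per foot
* LA — toe-tip height per leg plus the knee angle (hip-knee-ankle)
* AFC — mid-hip height and trunk orientation
* GAIT — per-side ankle horizontal excursion, ankle angle and wrist-to-hip
  distance (arm swing)
* POS — neck and mid-hip horizontal sway and trunk orientation
* PTOH / KTOH — 3-10 Hz band-passed index-fingertip vertical displacement
  per hand (tremor band)
* FE — all 46 facial action-unit intensity series (handled separately,
  no keypoint channels)
"""

from __future__ import annotations

from .signals import ChannelSpec

__all__ = ["motion_channels", "required_joints"]


def _per_hand(name: str, kind: str, joints: tuple[str, ...], **kw) -> list[ChannelSpec]:
    return [
        ChannelSpec(name=name, kind=kind, array="left_hand", joints=joints,
                    side="left", **kw),
        ChannelSpec(name=name, kind=kind, array="right_hand", joints=joints,
                    side="right", **kw),
    ]


def _per_leg(name: str, kind: str, joints_l: tuple[str, ...],
             joints_r: tuple[str, ...], **kw) -> list[ChannelSpec]:
    return [
        ChannelSpec(name=name, kind=kind, array="body", joints=joints_l,
                    side="left", **kw),
        ChannelSpec(name=name, kind=kind, array="body", joints=joints_r,
                    side="right", **kw),
    ]


_TREMOR_BAND = (3.0, 10.0)

_CHANNEL_MAP: dict[str, list[ChannelSpec]] = {
    "FT": _per_hand("tap_aperture", "distance", ("Thumb4", "Index4")),
    "HM": _per_hand(
        "hand_aperture", "aperture",
        ("Wrist", "Thumb4", "Index4", "Middle4", "Ring4", "Pinky4"),
    ),
    "PSOH": _per_hand("knuckle_line", "orientation", ("Index1", "Pinky1")),
    "TT": _per_leg("toe_height", "axis", ("LBigToe",), ("RBigToe",), axis="y"),
    "LA": (
        _per_leg("toe_height", "axis", ("LBigToe",), ("RBigToe",), axis="y")
        + _per_leg(
            "knee_angle", "angle",
            ("LHip", "LKnee", "LAnkle"), ("RHip", "RKnee", "RAnkle"),
        )
    ),
    "AFC": [
        ChannelSpec(name="hip_height", kind="axis", array="body",
                    joints=("MidHip",), axis="y"),
        ChannelSpec(name="trunk_line", kind="orientation", array="body",
                    joints=("MidHip", "Neck")),
    ],
    "GAIT": (
        _per_leg("ankle_x", "axis", ("LAnkle",), ("RAnkle",), axis="x")
        + _per_leg(
            "ankle_angle", "angle",
            ("LKnee", "LAnkle", "LBigToe"), ("RKnee", "RAnkle", "RBigToe"),
        )
        + _per_leg("arm_swing", "distance", ("LWrist", "LHip"), ("RWrist", "RHip"))
    ),
    "POS": [
        ChannelSpec(name="neck_sway", kind="axis", array="body",
                    joints=("Neck",), axis="x"),
        ChannelSpec(name="hip_sway", kind="axis", array="body",
                    joints=("MidHip",), axis="x"),
        ChannelSpec(name="trunk_line", kind="orientation", array="body",
                    joints=("MidHip", "Neck")),
    ],
    "PTOH": _per_hand("tremor_disp", "axis", ("Index4",), axis="y",
                      bandpass=_TREMOR_BAND),
    "KTOH": _per_hand("tremor_disp", "axis", ("Index4",), axis="y",
                      bandpass=_TREMOR_BAND),
    "FE": [],  # AU series; no keypoint channels
}


def motion_channels(motion: str) -> list[ChannelSpec]:
    """Channel specs for one motion (empty for FE: AU series are implicit)."""
    try:
        return list(_CHANNEL_MAP[motion])
    except KeyError:
        raise KeyError(f"unknown motion {motion!r}") from None


def required_joints(motion: str) -> dict[str, tuple[str, ...]]:
    """Joints each array must provide for this motion's channels.

    Always includes the normalization segment (Neck/MidHip, or
    Wrist/Middle1 for hand arrays).
    """
    req: dict[str, set[str]] = {}
    for spec in motion_channels(motion):
        req.setdefault(spec.array, set()).update(spec.joints)
    for array, joints in req.items():
        if array == "body":
            joints.update({"Neck", "MidHip"})
        else:
            joints.update({"Wrist", "Middle1"})
    return {k: tuple(sorted(v)) for k, v in req.items()}
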