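"""Named 1-D signals derived from clean recordings, and their cyclic structure.

The feature pipeline works on per-frame scalar channels: a joint coordinate
along one axis, the Euclidean distance between two joints, the interior angle
at a joint (degrees), or the image-plane orientation of a segment. Channels
are smoothed with a smoothing spline (generalized cross-validation picks the
penalty unless fixed) and their peaks and valleys located with prominence
and minimum-spacing rules, which anchors the cycle-kinematics features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.signal import butter, detrend, filtfilt, find_peaks

from .errors import SchemaError
from .recording import CleanRecording, _fill_gaps

__all__ = [
    "SignalChannel",
    "PeakValleySet",
    "ChannelSpec",
    "position_signal",
    "angle_signal",
    "extract_channel",
    "smooth_signal",
    "SmoothingConfig",
    "PeakConfig",
    "detect_peaks_valleys",
    "dominant_frequency",
]


@dataclass
class SignalChannel:
    """A named, optionally sided 1-D time series.

    ``kind`` is ``position`` (normalized body-size units), ``angle``
    (degrees in [0, 180]) or ``au`` (action-unit intensity).
    """

    name: str
    values: np.ndarray
    frame_rate: float
    side: str | None = None  # "left" | "right" | None
    kind: str = "position"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise SchemaError(f"channel {self.name!r}: need a 1-D series, length >= 2")
        if self.kind == "angle":
            v = self.values[np.isfinite(self.values)]
            if v.size and (v.min() < -1e-9 or v.max() > 180 + 1e-9):
                raise SchemaError(
                    f"channel {self.name!r}: angles must lie in [0, 180] degrees"
                )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate

    def replace_values(self, values: np.ndarray) -> "SignalChannel":
        return SignalChannel(
            name=self.name,
            values=values,
            frame_rate=self.frame_rate,
            side=self.side,
            kind=self.kind,
        )


@dataclass
class PeakValleySet:
    """Peak and valley frame indices with their prominences."""

    peak_indices: np.ndarray
    valley_indices: np.ndarray
    peak_prominences: np.ndarray
    valley_prominences: np.ndarray

    def __post_init__(self) -> None:
        for name in ("peak_indices", "valley_indices"):
            idx = np.asarray(getattr(self, name), dtype=int)
            if idx.size and np.any(np.diff(idx) <= 0):
                raise SchemaError(f"{name} must be strictly increasing")
            setattr(self, name, idx)
        self.peak_prominences = np.asarray(self.peak_prominences, dtype=float)
        self.valley_prominences = np.asarray(self.valley_prominences, dtype=float)

    @property
    def n_peaks(self) -> int:
        return int(self.peak_indices.size)

    @property
    def n_valleys(self) -> int:
        return int(self.valley_indices.size)


@dataclass(frozen=True)
class ChannelSpec:
    """Descriptor of how to derive one scalar channel from a recording.

    kind:
      axis        — coordinate of ``joints[0]`` along ``axis``
      distance    — Euclidean distance between ``joints[0]`` and ``joints[1]``
      angle       — interior angle at ``joints[1]`` of the triple
      orientation — image-plane angle of segment joints[0]->joints[1]
                    against the horizontal, folded into [0, 180)
      aperture    — mean distance from ``joints[0]`` to each of ``joints[1:]``
    ``bandpass`` optionally applies a Butterworth band-pass (Hz) to the
    extracted series (used for the tremor items).
    """

    name: str
    kind: str
    array: str  # "body" | "left_hand" | "right_hand"
    joints: tuple[str, ...]
    axis: str = "y"
    side: str | None = None
    bandpass: tuple[float, float] | None = None

    @property
    def signal_kind(self) -> str:
        return "angle" if self.kind in ("angle", "orientation") else "position"


def _joint_xy(rec: CleanRecording, array: str, joint: str) -> np.ndarray:
    if array not in rec.coords:
        raise SchemaError(
            f"recording {rec.subject_id}/{rec.motion} has no {array!r} array"
        )
    return rec.joint_xy(array, joint)


def position_signal(rec: CleanRecording, spec: ChannelSpec) -> SignalChannel:
    """Extract a position channel (axis coordinate, distance or aperture)."""
    if spec.kind == "axis":
        xy = _joint_xy(rec, spec.array, spec.joints[0])
        values = xy[:, 0] if spec.axis == "x" else xy[:, 1]
    elif spec.kind == "distance":
        a = _joint_xy(rec, spec.array, spec.joints[0])
        b = _joint_xy(rec, spec.array, spec.joints[1])
        values = np.linalg.norm(a - b, axis=1)
    elif spec.kind == "aperture":
        base = _joint_xy(rec, spec.array, spec.joints[0])
        dists = [
            np.linalg.norm(_joint_xy(rec, spec.array, j) - base, axis=1)
            for j in spec.joints[1:]
        ]
        values = np.mean(dists, axis=0)
    else:
        raise SchemaError(f"position_signal cannot build kind {spec.kind!r}")
    return SignalChannel(
        name=spec.name,
        values=values,
        frame_rate=rec.frame_rate,
        side=spec.side,
        kind="position",
    )


def angle_signal(
    rec: CleanRecording,
    joint_triple: tuple[str, str, str],
    array: str = "body",
    name: str | None = None,
    side: str | None = None,
) -> SignalChannel:
    """Per-frame interior angle (degrees) at the vertex of a joint triple.

    Frames where a limb vector collapses to zero length are marked missing
    and gap-filled as in preprocessing. Range of motion is then simply the
    max minus min of the returned series.
    """
    a, vertex, b = joint_triple
    if len({a, vertex, b}) != 3:
        raise SchemaError("angle needs three distinct joints")
    pa = _joint_xy(rec, array, a)
    pv = _joint_xy(rec, array, vertex)
    pb = _joint_xy(rec, array, b)
    u = pa - pv
    w = pb - pv
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, w) / (nu * nw)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    bad = (nu == 0) | (nw == 0)
    if bad.any():
        ang[bad] = np.nan
        ang = _fill_gaps(ang, max_gap=ang.size)  # always fill; angles stay bounded
        if np.isnan(ang).all():
            ang = np.zeros_like(ang)
    return SignalChannel(
        name=name or f"angle_{vertex}",
        values=ang,
        frame_rate=rec.frame_rate,
        side=side,
        kind="angle",
    )


def _orientation_signal(rec: CleanRecording, spec: ChannelSpec) -> SignalChannel:
    a = _joint_xy(rec, spec.array, spec.joints[0])
    b = _joint_xy(rec, spec.array, spec.joints[1])
    d = b - a
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))  # (-180, 180]
    ang = np.mod(ang, 180.0)  # fold: undirected line orientation
    return SignalChannel(
        name=spec.name,
        values=ang,
        frame_rate=rec.frame_rate,
        side=spec.side,
        kind="angle",
    )


def _bandpass(values: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    nyq = fs / 2.0
    high = min(high, 0.99 * nyq)
    b, a = butter(2, [low / nyq, high / nyq], btype="band")
    return filtfilt(b, a, values)


def extract_channel(rec: CleanRecording, spec: ChannelSpec) -> SignalChannel:
    """Dispatch a ChannelSpec to the right extractor, applying any band-pass."""
    if spec.kind == "angle":
        sig = angle_signal(
            rec, spec.joints, array=spec.array, name=spec.name, side=spec.side
        )
    elif spec.kind == "orientation":
        sig = _orientation_signal(rec, spec)
    else:
        sig = position_signal(rec, spec)
    if spec.bandpass is not None:
        low, high = spec.bandpass
        filtered = _bandpass(sig.values, rec.frame_rate, low, high)
        # A band-passed angle is a displacement, not an angle in [0, 180].
        sig = SignalChannel(
            name=sig.name,
            values=filtered,
            frame_rate=sig.frame_rate,
            side=sig.side,
            kind="position",
        )
    return sig


@dataclass
class SmoothingConfig:
    """Smoothing-spline settings; ``lam=None`` selects the penalty by GCV."""

    lam: float | None = None


def smooth_signal(
    sig: SignalChannel, config: SmoothingConfig | None = None
) -> SignalChannel:
    """Smoothing-spline fit of the channel, evaluated at the original times.

    Linear trends pass through unpenalized (they lie in the penalty null
    space), so a noiseless straight line is reproduced exactly.
    """
    config = config or SmoothingConfig()
    if sig.values.size < 4:
        raise SchemaError("smoothing needs at least 4 samples")
    if np.ptp(sig.times) == 0:
        raise SchemaError("all-equal time stamps")
    y = sig.values
    if np.ptp(y) == 0:
        return sig.replace_values(y.copy())  # constant is a fixed point
    # Fit against the frame index rather than seconds: the GCV search for
    # the penalty is parameterised for unit-spaced abscissae and
    # over-smooths badly on sub-second spacing.
    x = np.arange(y.size, dtype=float)
    spl = make_smoothing_spline(x, y, lam=config.lam)
    smoothed = spl(x)
    if sig.kind == "angle":
        smoothed = np.clip(smoothed, 0.0, 180.0)
    return sig.replace_values(smoothed)


def dominant_frequency(
    values: np.ndarray,
    frame_rate: float,
    band: tuple[float, float] = (0.5, 10.0),
) -> tuple[float, bool]:
    """Dominant frequency (Hz) of the detrended, Hann-windowed signal.

    Returns ``(frequency, flagged)``; a constant or power-free signal yields
    ``(0.0, True)``.
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0 or x.size < 4:
        return 0.0, True
    xd = detrend(x)
    w = np.hanning(x.size)
    spec = np.abs(np.fft.rfft(xd * w)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / frame_rate)
    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any() or spec[in_band].max() <= 0:
        return 0.0, True
    k = np.argmax(np.where(in_band, spec, -np.inf))
    return float(freqs[k]), False


@dataclass
class PeakConfig:
    """Peak/valley detection settings.

    prominence must exceed ``prom_frac`` x the interquartile range of the
    signal (peak-to-peak range when the IQR vanishes), and extrema of the
    same type must be at least ``min_period_frac`` / dominant-frequency
    apart. Defaults reject tremor ripple riding on voluntary cycles.
    """

    prom_frac: float = 0.25
    min_period_frac: float = 0.5


def _enforce_alternation(
    peaks: np.ndarray,
    peak_prom: np.ndarray,
    valleys: np.ndarray,
    valley_prom: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Discard the lower-prominence members of same-type runs."""
    if peaks.size == 0 or valleys.size == 0:
        return peaks, peak_prom, valleys, valley_prom
    events = [(int(i), 1, float(p)) for i, p in zip(peaks, peak_prom)]
    events += [(int(i), -1, float(p)) for i, p in zip(valleys, valley_prom)]
    events.sort()
    kept: list[tuple[int, int, float]] = []
    for ev in events:
        if kept and kept[-1][1] == ev[1]:
            if ev[2] > kept[-1][2]:
                kept[-1] = ev
        else:
            kept.append(ev)
    p_idx = np.array([e[0] for e in kept if e[1] == 1], dtype=int)
    p_pr = np.array([e[2] for e in kept if e[1] == 1])
    v_idx = np.array([e[0] for e in kept if e[1] == -1], dtype=int)
    v_pr = np.array([e[2] for e in kept if e[1] == -1])
    return p_idx, p_pr, v_idx, v_pr


def detect_peaks_valleys(
    sig: SignalChannel, config: PeakConfig | None = None
) -> PeakValleySet:
    """Locate alternating peaks and valleys of a (smoothed) channel."""
    config = config or PeakConfig()
    x = sig.values
    if np.ptp(x) == 0:
        empty = np.array([], dtype=int)
        return PeakValleySet(empty, empty.copy(), np.array([]), np.array([]))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = iqr if iqr > 0 else float(np.ptp(x))
    prom = config.prom_frac * scale
    f_dom, flagged = dominant_frequency(x, sig.frame_rate)
    distance = None
    if not flagged and f_dom > 0:
        distance = max(1, int(round(config.min_period_frac / f_dom * sig.frame_rate)))
    peaks, pprops = find_peaks(x, prominence=prom, distance=distance)
    valleys, vprops = find_peaks(-x, prominence=prom, distance=distance)
    p_idx, p_pr, v_idx, v_pr = _enforce_alternation(
        peaks, pprops["prominences"], valleys, vprops["prominences"]
    )
    return PeakValleySet(p_idx, v_idx, p_pr, v_pr)
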