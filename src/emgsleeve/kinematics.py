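"""Glove kinematics: 18 strain sensors -> 23 named joint angles on the bin clock.

The motion-capture glove measures 18 joints directly (per-finger MPJ, PIJ
and abduction; thumb MPJ, abduction and rotation; palm arch; wrist pitch
and yaw).  The five distal joints (four finger DIJs and the thumb IJ) are
not instrumented and are derived from the same digit's MPJ angle via a
fixed quadratic coupling.  Angle tracks are resampled to the 10 Hz feature
bin clock and causally smoothed before being used as regression targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlignmentError, ConfigurationError

log = logging.getLogger(__name__)

FINGERS = ("index", "middle", "ring", "pinky")

#: Joints read directly from the 18 glove strain sensors.
DIRECT_JOINTS: tuple[str, ...] = tuple(
    f"{f}_{j}" for f in FINGERS for j in ("mpj", "pij", "abd")
) + ("thumb_mpj", "thumb_abd", "thumb_rot", "palm_arch", "wrist_pitch", "wrist_yaw")

#: Joints derived from MPJ angles (distal interphalangeal + thumb IJ).
DERIVED_JOINTS: tuple[str, ...] = tuple(f"{f}_dij" for f in FINGERS) + ("thumb_ij",)

#: Full 23-joint registry, fixed ordering used throughout the package.
JOINT_NAMES: tuple[str, ...] = DIRECT_JOINTS + DERIVED_JOINTS

#: MPJ angle that drives each derived distal joint.
DISTAL_SOURCE: dict[str, str] = {f"{f}_dij": f"{f}_mpj" for f in FINGERS}
DISTAL_SOURCE["thumb_ij"] = "thumb_mpj"

#: Joints dropped in group analyses (damaged index sensor convention),
#: leaving a 21-target regression task.
GROUP_EXCLUDED: tuple[str, ...] = ("index_mpj", "index_dij")

N_SENSORS = 18
N_JOINTS = 23


def default_sensor_mapping() -> dict[str, int]:
    """One-to-one mapping from directly measured joint name to sensor row."""
    return {name: i for i, name in enumerate(DIRECT_JOINTS)}


@dataclass
class JointAngleTrack:
    """Named joint-angle trajectories in degrees.

    ``angles`` has one row per joint in ``joint_names`` order.  The track
    lives either on the raw glove clock (90 Hz) or, after
    :func:`resample_to_bins`, on the 10 Hz feature bin clock with
    ``times_s`` holding per-bin end times.
    """

    angles: np.ndarray
    joint_names: tuple[str, ...]
    fs_hz: float
    t0: float = 0.0
    times_s: np.ndarray | None = None
    smoothed: bool = False
    excluded_joints: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[0] != len(self.joint_names):
            raise ConfigurationError(
                f"angles must be (n_joints={len(self.joint_names)}) x samples, "
                f"got {self.angles.shape}"
            )
        if not np.all(np.isfinite(self.angles)):
            raise ConfigurationError("joint angles must be finite")

    @property
    def sample_times(self) -> np.ndarray:
        if self.times_s is not None:
            return self.times_s
        return self.t0 + np.arange(self.angles.shape[1]) / self.fs_hz

    def drop_joints(self, names: tuple[str, ...] = GROUP_EXCLUDED) -> "JointAngleTrack":
        """Return a track without the named joints (group-analysis exclusion)."""
        missing = [n for n in names if n not in self.joint_names]
        if missing:
            raise ConfigurationError(f"cannot exclude unknown joints {missing}")
        keep = [i for i, n in enumerate(self.joint_names) if n not in names]
        return replace(
            self,
            angles=self.angles[keep],
            joint_names=tuple(n for n in self.joint_names if n not in names),
            excluded_joints=self.excluded_joints + tuple(names),
        )


def derive_distal(mpj_deg):
    """Distal-joint angle derived from the driving MPJ angle.

    The coupling is 30% of the squared MPJ angle, evaluated in radians and
    returned in degrees: DIJ = deg(0.3 * rad(MPJ)^2).  Evaluating the square
    in degrees would produce absurd magnitudes (0.3 * 90^2 = 2430 deg), so
    the radian convention is used.
    """
    theta = np.deg2rad(np.asarray(mpj_deg, dtype=float))
    return np.rad2deg(0.3 * theta**2)


def derive_joint_angles(glove, mapping: dict[str, int] | None = None) -> JointAngleTrack:
    """Convert an 18-sensor glove track into the 23-joint angle track.

    ``mapping`` assigns each directly measured joint to a sensor row; the
    default is the identity ordering over :data:`DIRECT_JOINTS`.  Distal
    joints are filled in via :func:`derive_distal`.
    """
    if mapping is None:
        mapping = default_sensor_mapping()
    missing = [n for n in DIRECT_JOINTS if n not in mapping]
    if missing:
        raise ConfigurationError(f"sensor mapping missing joints: {missing}")
    if glove.sensors.shape[0] != N_SENSORS:
        raise ConfigurationError(
            f"expected {N_SENSORS} sensor rows, got {glove.sensors.shape[0]}"
        )
    n = glove.sensors.shape[1]
    angles = np.zeros((N_JOINTS, n))
    for j, name in enumerate(DIRECT_JOINTS):
        angles[j] = glove.sensors[mapping[name]]
    name_to_row = {n_: i for i, n_ in enumerate(JOINT_NAMES)}
    for name in DERIVED_JOINTS:
        src = name_to_row[DISTAL_SOURCE[name]]
        angles[name_to_row[name]] = derive_distal(angles[src])
    return JointAngleTrack(
        angles=angles, joint_names=JOINT_NAMES, fs_hz=glove.fs_hz, t0=glove.t0
    )


def resample_to_bins(
    track: JointAngleTrack, bin_times_s: np.ndarray, bin_s: float = 0.1
) -> JointAngleTrack:
    """Resample a glove-rate track to one angle vector per RMS bin.

    Each 100 ms bin takes the mean of the glove samples falling inside it
    (windowed mean rather than decimation, robust to sample jitter).
    ``bin_times_s`` are bin end times; bin i covers [t_end - bin_s, t_end).
    """
    bin_times_s = np.asarray(bin_times_s, dtype=float)
    t = track.sample_times
    starts = np.searchsorted(t, bin_times_s - bin_s, side="left")
    stops = np.searchsorted(t, bin_times_s, side="left")
    if np.any(stops <= starts):
        raise AlignmentError("glove track does not cover all requested bins")
    csum = np.concatenate(
        [np.zeros((track.angles.shape[0], 1)), np.cumsum(track.angles, axis=1)], axis=1
    )
    sums = csum[:, stops] - csum[:, starts]
    means = sums / (stops - starts)
    return replace(
        track, angles=means, fs_hz=1.0 / bin_s, times_s=bin_times_s, t0=bin_times_s[0]
    )


def smooth_angles(track: JointAngleTrack, window_bins: int = 5) -> JointAngleTrack:
    """Causal trailing moving average over ``window_bins`` bins.

    The current bin is averaged with the preceding ``window_bins - 1`` bins;
    early bins average over the history available so far.
    """
    if window_bins < 1:
        raise ConfigurationError("window_bins must be >= 1")
    if window_bins == 1:
        return replace(track, smoothed=True)
    a = track.angles
    csum = np.concatenate([np.zeros((a.shape[0], 1)), np.cumsum(a, axis=1)], axis=1)
    n = a.shape[1]
    idx = np.arange(n)
    lo = np.maximum(idx - window_bins + 1, 0)
    out = (csum[:, idx + 1] - csum[:, lo]) / (idx - lo + 1)
    return replace(track, angles=out, smoothed=True)
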