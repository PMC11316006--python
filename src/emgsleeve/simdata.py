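"""Synthetic sleeve EMG, glove kinematics, and cue schedules.

The generator emulates the statistical structure the decoding pipeline
assumes: gesture-specific spatial activation patterns over the sleeve's
electrode grid, band-limited (20-400 Hz) noise carriers modulated by
trapezoidal effort envelopes, 60 Hz line interference, per-trial reaction
delays between cue presentation and muscle onset, and smooth glove sensor
trajectories time-locked to the same delays.  Cue schedules follow the two
recording paradigms: *sequential* blocks of 10 repetitions of one movement
with interleaved rest, and *mixed* blocks interleaving 3-6 movements with
5 repetitions each in shuffled order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import kinematics as kin
from .errors import ConfigurationError, ScheduleError

#: Label reserved for the rest class.
REST = "Rest"

EMG_FS_HZ = 3000.0
GLOVE_FS_HZ = 90.0

#: Named sleeve sizes -> bipolar channel counts.
SLEEVE_SIZES = {"small": 59, "medium": 70, "large": 75}
_GRID_ROWS = 5  # electrode rows around the forearm circumference


# ---------------------------------------------------------------------------
# layouts and gestures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SleeveLayout:
    """Electrode-grid geometry of one sleeve size.

    ``grid_coords`` holds per-channel (row, col) positions on the flattened
    sleeve grid; rows run around the forearm, columns along it.
    """

    size_tag: str
    n_channels: int
    grid_coords: np.ndarray

    def __post_init__(self) -> None:
        expected = SLEEVE_SIZES.get(self.size_tag)
        if expected is not None and expected != self.n_channels:
            raise ConfigurationError(
                f"{self.size_tag} sleeve has {expected} channels, got {self.n_channels}"
            )
        coords = np.asarray(self.grid_coords)
        if coords.shape != (self.n_channels, 2):
            raise ConfigurationError("grid_coords must be (n_channels, 2)")
        if len({tuple(c) for c in coords.tolist()}) != self.n_channels:
            raise ConfigurationError("grid_coords must be unique per channel")

    @classmethod
    def from_size(cls, size_tag: str) -> "SleeveLayout":
        if size_tag not in SLEEVE_SIZES:
            raise ConfigurationError(f"unknown sleeve size {size_tag!r}")
        return cls._grid(size_tag, SLEEVE_SIZES[size_tag])

    @classmethod
    def custom(cls, n_channels: int, size_tag: str = "custom") -> "SleeveLayout":
        """Small test layouts with the same grid convention."""
        if size_tag in SLEEVE_SIZES:
            raise ConfigurationError("use from_size for named sleeve sizes")
        return cls._grid(size_tag, n_channels)

    @classmethod
    def _grid(cls, tag: str, n: int) -> "SleeveLayout":
        n_cols = math.ceil(n / _GRID_ROWS)
        idx = np.arange(n)
        coords = np.stack([idx // n_cols, idx % n_cols], axis=1).astype(float)
        return cls(size_tag=tag, n_channels=n, grid_coords=coords)

    @property
    def normalized_coords(self) -> np.ndarray:
        """Coordinates scaled to [0, 1]^2 for cross-layout comparison."""
        c = self.grid_coords.astype(float)
        span = np.maximum(c.max(axis=0), 1.0)
        return c / span


@dataclass
class GestureSpec:
    """Spatial activation pattern and target hand pose of one gesture."""

    gesture_id: str
    activation_map: np.ndarray
    target_pose: np.ndarray  # 23 joint angles, degrees, kinematics order
    envelope_rise_ms: float = 150.0
    envelope_fall_ms: float = 200.0

    def __post_init__(self) -> None:
        self.activation_map = np.asarray(self.activation_map, dtype=float)
        self.target_pose = np.asarray(self.target_pose, dtype=float)
        if np.any(self.activation_map < 0):
            raise ConfigurationError("activation_map must be nonnegative")
        if self.target_pose.shape != (kin.N_JOINTS,):
            raise ConfigurationError(
                f"target_pose must have {kin.N_JOINTS} entries"
            )
        if self.gesture_id != REST and not np.any(self.activation_map > 0):
            raise ConfigurationError(
                "non-rest gesture needs a strictly positive activation entry"
            )
        if self.gesture_id == REST and np.any(self.activation_map > 0):
            raise ConfigurationError("rest gesture must have an all-zero map")


def rest_spec(layout: SleeveLayout) -> GestureSpec:
    """Rest: no activation, neutral (all-zero) pose."""
    return GestureSpec(
        gesture_id=REST,
        activation_map=np.zeros(layout.n_channels),
        target_pose=np.zeros(kin.N_JOINTS),
    )


def _random_pose(rng: np.random.Generator) -> np.ndarray:
    """Draw a plausible hand pose (degrees) with consistent distal joints."""
    pose = {}
    for f in kin.FINGERS:
        pose[f"{f}_mpj"] = rng.uniform(5.0, 80.0)
        pose[f"{f}_pij"] = rng.uniform(0.0, 90.0)
        pose[f"{f}_abd"] = rng.uniform(-15.0, 15.0)
    pose["thumb_mpj"] = rng.uniform(0.0, 55.0)
    pose["thumb_abd"] = rng.uniform(-30.0, 30.0)
    pose["thumb_rot"] = rng.uniform(-45.0, 45.0)
    pose["palm_arch"] = rng.uniform(0.0, 20.0)
    pose["wrist_pitch"] = rng.uniform(-40.0, 40.0)
    pose["wrist_yaw"] = rng.uniform(-20.0, 20.0)
    for name, src in kin.DISTAL_SOURCE.items():
        pose[name] = float(kin.derive_distal(pose[src]))
    return np.array([pose[n] for n in kin.JOINT_NAMES])


def _blob_map(layout: SleeveLayout, rng: np.random.Generator) -> np.ndarray:
    """1-3 Gaussian blobs on the normalized grid, peak-normalized to 1."""
    coords = layout.normalized_coords
    amap = np.zeros(layout.n_channels)
    for _ in range(rng.integers(1, 4)):
        center = rng.uniform(0.0, 1.0, size=2)
        sigma = rng.uniform(0.10, 0.30)
        amp = rng.uniform(0.5, 1.0)
        d2 = np.sum((coords - center) ** 2, axis=1)
        amap += amp * np.exp(-d2 / (2 * sigma**2))
    return amap / amap.max()


def make_gesture_set(
    labels: list[str],
    layout: SleeveLayout,
    seed: int,
    max_pairwise_corr: float = 0.9,
    max_tries: int = 200,
) -> dict[str, GestureSpec]:
    """Random gesture set with separable-but-confusable activation maps.

    Pairwise correlations between activation maps are kept below
    ``max_pairwise_corr`` by resampling, so classes overlap spatially the
    way forearm muscle groups do without collapsing onto each other.
    Always includes a rest spec under the :data:`REST` label.
    """
    if REST in labels:
        raise ScheduleError(f"{REST!r} is reserved; list movements only")
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    for _ in labels:
        for _try in range(max_tries):
            cand = _blob_map(layout, rng)
            if all(
                abs(np.corrcoef(cand, m)[0, 1]) < max_pairwise_corr for m in maps
            ):
                maps.append(cand)
                break
        else:
            raise ConfigurationError(
                "could not draw sufficiently distinct activation maps"
            )
    specs = {
        lab: GestureSpec(lab, amap, _random_pose(rng))
        for lab, amap in zip(labels, maps)
    }
    specs[REST] = rest_spec(layout)
    return specs


def jitter_gesture_set(
    gestures: dict[str, GestureSpec],
    seed: int,
    map_jitter_sd: float = 0.15,
    gain_sd: float = 0.10,
) -> dict[str, GestureSpec]:
    """Per-subject variant of a gesture set (for synthetic cohorts).

    Activation maps get multiplicative channel noise plus a shared
    per-channel gain vector, emulating anatomical and electrode-contact
    differences between wearers of the same sleeve.
    """
    rng = np.random.default_rng(seed)
    n = next(iter(gestures.values())).activation_map.shape[0]
    gains = np.clip(rng.normal(1.0, gain_sd, size=n), 0.2, None)
    out = {}
    for lab, spec in gestures.items():
        if lab == REST:
            out[lab] = spec
            continue
        amap = spec.activation_map * gains
        amap = amap * np.clip(rng.normal(1.0, map_jitter_sd, size=n), 0.0, None)
        if amap.max() > 0:
            amap = amap / amap.max()
        out[lab] = GestureSpec(
            lab, amap, spec.target_pose, spec.envelope_rise_ms, spec.envelope_fall_ms
        )
    return out


# ---------------------------------------------------------------------------
# cue schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CueEvent:
    label: str
    onset_s: float
    offset_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.onset_s + self.offset_s)


@dataclass
class CueSchedule:
    """Ordered, non-overlapping cue events with paradigm/block tags."""

    events: list[CueEvent]
    paradigm: str  # sequential | mixed
    block_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.events, self.events[1:]):
            if b.onset_s < a.offset_s - 1e-9:
                raise ScheduleError("cue events must be time-ordered, non-overlapping")
        if not self.block_ids:
            self.block_ids = [0] * len(self.events)
        if len(self.block_ids) != len(self.events):
            raise ScheduleError("block_ids must match events")

    @property
    def movement_events(self) -> list[CueEvent]:
        return [e for e in self.events if e.label != REST]

    @property
    def movement_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.events) if e.label != REST]

    @property
    def labels(self) -> list[str]:
        return sorted({e.label for e in self.movement_events})

    @property
    def end_s(self) -> float:
        return self.events[-1].offset_s if self.events else 0.0


@dataclass
class TrialLatencies:
    """Injected reaction delays per movement cue (ground truth)."""

    event_indices: np.ndarray  # indices into CueSchedule.events
    onset_delay_ms: np.ndarray
    offset_delay_ms: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.onset_delay_ms < 0) or np.any(self.offset_delay_ms < 0):
            raise ConfigurationError("reaction delays must be >= 0")


def _interleave(
    movement_labels: list[str],
    cue_dur_range_s: tuple[float, float],
    rest_dur_range_s: tuple[float, float],
    rng: np.random.Generator,
    paradigm: str,
    block_of: list[int],
) -> CueSchedule:
    """Rest before every movement cue plus one trailing rest."""
    events: list[CueEvent] = []
    blocks: list[int] = []
    t = 0.0
    for lab, blk in zip(movement_labels, block_of):
        rd = rng.uniform(*rest_dur_range_s)
        events.append(CueEvent(REST, t, t + rd))
        blocks.append(blk)
        t += rd
        cd = rng.uniform(*cue_dur_range_s)
        events.append(CueEvent(lab, t, t + cd))
        blocks.append(blk)
        t += cd
    rd = rng.uniform(*rest_dur_range_s)
    events.append(CueEvent(REST, t, t + rd))
    blocks.append(block_of[-1] if block_of else 0)
    return CueSchedule(events=events, paradigm=paradigm, block_ids=blocks)


def make_sequential_schedule(
    movements: list[str],
    reps: int = 10,
    cue_dur_range_s: tuple[float, float] = (2.0, 3.0),
    rest_dur_range_s: tuple[float, float] = (2.0, 3.0),
    seed: int = 0,
) -> CueSchedule:
    """Sequential paradigm: per movement, ``reps`` consecutive attempts.

    Each movement's attempts form one data block; rest is interleaved
    between all attempts.  Cue and rest durations are drawn uniformly from
    the given ranges (2-3 s defaults).
    """
    if not movements:
        raise ScheduleError("movement list must be non-empty")
    if reps < 1:
        raise ScheduleError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    labels = [m for m in movements for _ in range(reps)]
    blocks = [bi for bi, _m in enumerate(movements) for _ in range(reps)]
    return _interleave(labels, cue_dur_range_s, rest_dur_range_s, rng, "sequential", blocks)


def _shuffle_no_adjacent(items: list[str], rng: np.random.Generator) -> list[str]:
    """Random order avoiding identical consecutive labels unless forced.

    Greedy draw among the remaining labels excluding the previous one,
    biased toward the most frequent remainder so the sequence never paints
    itself into a corner except on genuine exhaustion.
    """
    counts: dict[str, int] = {}
    for it in items:
        counts[it] = counts.get(it, 0) + 1
    seq: list[str] = []
    prev = None
    while counts:
        options = [k for k in counts if k != prev] or list(counts)
        max_c = max(counts[k] for k in options)
        # must place a maximal label if it holds more than half the remainder
        if 2 * max_c > sum(counts.values()):
            options = [k for k in options if counts[k] == max_c]
        pick = options[int(rng.integers(len(options)))]
        seq.append(pick)
        counts[pick] -= 1
        if counts[pick] == 0:
            del counts[pick]
        prev = pick
    return seq


def make_mixed_schedule(
    movement_pool: list[str],
    reps_per_movement: int = 5,
    movements_per_block: tuple[int, int] = (3, 6),
    cue_dur_range_s: tuple[float, float] = (2.0, 3.0),
    rest_dur_range_s: tuple[float, float] = (2.0, 3.0),
    seed: int = 0,
) -> CueSchedule:
    """Mixed paradigm: blocks of 3-6 distinct movements, shuffled, 5 reps each."""
    lo, hi = movements_per_block
    if reps_per_movement < 1:
        raise ScheduleError("reps_per_movement must be >= 1")
    if len(movement_pool) < hi and len(movement_pool) < lo:
        raise ScheduleError("movement pool smaller than minimum block size")
    rng = np.random.default_rng(seed)
    pool = [movement_pool[i] for i in rng.permutation(len(movement_pool))]
    block_sizes: list[int] = []
    remaining = len(pool)
    while remaining > 0:
        if remaining <= hi:
            size = remaining
        else:
            # keep the remainder feasible: zero or at least one full block
            feasible = [s for s in range(lo, hi + 1) if remaining - s >= lo]
            size = int(feasible[int(rng.integers(len(feasible)))])
        block_sizes.append(size)
        remaining -= size
    labels: list[str] = []
    blocks: list[int] = []
    start = 0
    for bi, size in enumerate(block_sizes):
        members = pool[start : start + size]
        start += size
        seq = _shuffle_no_adjacent(members * reps_per_movement, rng)
        labels.extend(seq)
        blocks.extend([bi] * len(seq))
    return _interleave(labels, cue_dur_range_s, rest_dur_range_s, rng, "mixed", blocks)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


@dataclass
class EMGRecording:
    """Raw channels x samples EMG with sleeve metadata."""

    signal: np.ndarray
    fs_hz: float
    layout: SleeveLayout
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.signal.ndim != 2 or self.signal.shape[0] != self.layout.n_channels:
            raise ConfigurationError(
                "signal must be (layout.n_channels, samples): "
                f"got {self.signal.shape} for {self.layout.n_channels} channels"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ConfigurationError("EMG signal must be finite")

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs_hz


@dataclass
class GloveTrack:
    """18 raw strain-sensor rows at the glove sampling rate."""

    sensors: np.ndarray
    fs_hz: float = GLOVE_FS_HZ
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.sensors.ndim != 2 or self.sensors.shape[0] != kin.N_SENSORS:
            raise ConfigurationError(f"glove track needs {kin.N_SENSORS} sensor rows")


def _bandlimited_noise(
    n_channels: int,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    band: tuple[float, float] = (20.0, 400.0),
) -> np.ndarray:
    """Unit-RMS white noise shaped to the 20-400 Hz EMG band.

    Order-8 shaping keeps out-of-band carrier power below 5% of in-band
    power (the generator's spectral contract).
    """
    sos = sps.butter(8, band, btype="bandpass", fs=fs, output="sos")
    x = rng.standard_normal((n_channels, n_samples)).astype(np.float32)
    x = sps.sosfilt(sos, x, axis=1).astype(np.float32)
    x /= x.std(axis=1, keepdims=True)
    return x


def _raised_cosine(n: int) -> np.ndarray:
    """Smooth 0->1 transition over n samples."""
    return 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n)))


def simulate_recording(
    schedule: CueSchedule,
    gestures: dict[str, GestureSpec],
    layout: SleeveLayout,
    reaction_model: tuple[float, float, float] = (500.0, 330.0, 100.0),
    snr: float = 10.0,
    seed: int = 0,
    fs_hz: float = EMG_FS_HZ,
    glove_fs_hz: float = GLOVE_FS_HZ,
    baseline_rms: float = 1.0,
    line_amp_frac: float = 0.10,
    effort_jitter: float = 0.20,
    sensor_noise_sd_deg: float = 0.5,
    tail_s: float = 1.0,
) -> tuple[EMGRecording, GloveTrack, TrialLatencies]:
    """Generate one synthetic session from a cue schedule.

    Channel c is built as ``baseline_noise + A * activation[g][c] *
    envelope_g(t) * carrier_c(t) + line60(t)`` where the carrier is
    band-limited unit-RMS noise, the envelope is a trapezoid whose rise
    starts ``onset_delay`` after cue onset and whose fall starts
    ``offset_delay`` after cue offset, and ``A = snr * baseline_rms`` so
    that ``snr`` is the plateau carrier-to-baseline RMS ratio on a
    fully-active channel.  Per-trial plateau amplitude is jittered by
    ``effort_jitter`` to emulate submaximal-effort variability.  Delays are
    truncated-normal draws from ``reaction_model = (mean_on_ms,
    mean_off_ms, sd_ms)`` and are returned as ground truth.  Glove sensors
    follow raised-cosine transitions between poses locked to the same
    delays, plus Gaussian sensor noise.  Identical inputs and seed give
    identical outputs.
    """
    if snr <= 0:
        raise ConfigurationError("snr must be > 0")
    for e in schedule.movement_events:
        if e.label not in gestures:
            raise ConfigurationError(f"no GestureSpec for scheduled label {e.label!r}")
    rng = np.random.default_rng(seed)
    mean_on, mean_off, sd = reaction_model
    n_samples = int(round((schedule.end_s + tail_s) * fs_hz))

    emg = baseline_rms * _bandlimited_noise(layout.n_channels, n_samples, fs_hz, rng)
    carrier = _bandlimited_noise(layout.n_channels, n_samples, fs_hz, rng)
    amp = snr * baseline_rms

    move_idx = schedule.movement_indices
    on_delays = np.maximum(rng.normal(mean_on, sd, size=len(move_idx)), 0.0)
    off_delays = np.maximum(rng.normal(mean_off, sd, size=len(move_idx)), 0.0)

    # glove pose track assembled at glove rate alongside the EMG envelopes
    n_glove = int(round((schedule.end_s + tail_s) * glove_fs_hz))
    tg = np.arange(n_glove) / glove_fs_hz
    rest_pose = gestures.get(REST, rest_spec(layout)).target_pose
    pose = np.tile(rest_pose[:, None], (1, n_glove)).astype(float)

    for k, ei in enumerate(move_idx):
        ev = schedule.events[ei]
        spec = gestures[ev.label]
        d_on = on_delays[k] / 1000.0
        d_off = off_delays[k] / 1000.0
        rise = spec.envelope_rise_ms / 1000.0
        fall = spec.envelope_fall_ms / 1000.0
        t_rise = ev.onset_s + d_on
        t_fall = ev.offset_s + d_off
        plateau = amp * (1.0 + rng.uniform(-effort_jitter, effort_jitter))

        i0 = max(int(t_rise * fs_hz), 0)
        i1 = min(int((t_fall + fall) * fs_hz), n_samples)
        if i1 > i0:
            t = np.arange(i0, i1) / fs_hz
            env = np.clip((t - t_rise) / max(rise, 1e-9), 0.0, 1.0)
            env = np.minimum(env, np.clip((t_fall + fall - t) / max(fall, 1e-9), 0.0, 1.0))
            env = (plateau * env).astype(np.float32)
            emg[:, i0:i1] += (
                spec.activation_map[:, None].astype(np.float32)
                * env[None, :]
                * carrier[:, i0:i1]
            )

        # glove transition: rest -> target over the rise, back over the fall
        up = (tg >= t_rise) & (tg < t_rise + rise)
        hold = (tg >= t_rise + rise) & (tg < t_fall)
        down = (tg >= t_fall) & (tg < t_fall + fall)
        delta = (spec.target_pose - rest_pose)[:, None]
        if up.any():
            frac = 0.5 * (1 - np.cos(np.pi * (tg[up] - t_rise) / rise))
            pose[:, up] = rest_pose[:, None] + delta * frac[None, :]
        if hold.any():
            pose[:, hold] = spec.target_pose[:, None]
        if down.any():
            frac = 0.5 * (1 + np.cos(np.pi * (tg[down] - t_fall) / fall))
            pose[:, down] = rest_pose[:, None] + delta * frac[None, :]

    # mains interference, common across channels, relative to active carrier RMS
    t = (np.arange(n_samples) / fs_hz).astype(np.float32)
    line = line_amp_frac * amp * np.sqrt(2.0) * np.sin(
        2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi)
    ).astype(np.float32)
    emg += line[None, :]

    direct_rows = [kin.JOINT_NAMES.index(n) for n in kin.DIRECT_JOINTS]
    sensors = pose[direct_rows] + rng.normal(
        0.0, sensor_noise_sd_deg, size=(kin.N_SENSORS, n_glove)
    )

    rec = EMGRecording(signal=emg, fs_hz=fs_hz, layout=layout)
    glove = GloveTrack(sensors=sensors, fs_hz=glove_fs_hz)
    lat = TrialLatencies(
        event_indices=np.array(move_idx),
        onset_delay_ms=on_delays,
        offset_delay_ms=off_delays,
    )
    return rec, glove, lat
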