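"""Ground-truth label alignment: rasterization, mid-windows, cue shifting.

On-screen cues lead the actual muscle activity by the participant's
reaction time, so labels rasterized straight from the cue schedule are
misaligned with the EMG.  Three remedies are implemented: a *static*
shift that delays every cue boundary by a fixed amount; the *mid-window*
extraction that keeps only the central 1 s of each cue (avoiding
transitions altogether); and a *dynamic* shift that relocates each cue
edge to the steepest slope of aggregate RMS activity nearby, found with a
minimum-residuals sweep (two-segment least-squares changepoint), which
also yields a per-trial reaction-time estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError
from .simdata import REST, CueEvent, CueSchedule

log = logging.getLogger(__name__)

BIN_S = 0.1


@dataclass
class AlignedLabels:
    """Per-bin labels on the bin clock plus the events that produced them."""

    labels: np.ndarray  # dtype=object, one label per bin
    bin_times_s: np.ndarray
    method: str  # none | mid_window | static(...) | dynamic
    events: list[CueEvent] = field(default_factory=list)  # shifted events
    onset_shift_ms: np.ndarray | None = None  # per movement event
    offset_shift_ms: np.ndarray | None = None
    mask: np.ndarray | None = None  # mid-window bin mask


@dataclass(frozen=True)
class SweepConfig:
    """Parameters of the minimum-residuals changepoint sweep."""

    search_window_ms: float = 1000.0  # half-width around each cue edge
    min_segment_bins: int = 2
    reaction_floor_ms: float = -200.0  # anticipation allowance
    fallback_shift_ms: float = 400.0  # used when the window has no slope
    flat_tol: float = 1e-10
    # second, narrow sweep centered on the coarse breakpoint; spans the
    # activity transition (~150 ms rise) plus margin, removing the bias the
    # flat plateau induces on the wide-window fit.  0 disables refinement.
    refine_halfwidth_ms: float = 400.0


def rasterize(
    events: list[CueEvent] | CueSchedule,
    bin_times_s: np.ndarray,
    bin_s: float = BIN_S,
    rest_label: str = REST,
) -> np.ndarray:
    """Label each bin by the event containing its midpoint; gaps are rest.

    A boundary falling exactly on a bin midpoint assigns the bin to the
    later event (events are processed in order with half-open extents
    [onset, offset)).
    """
    if isinstance(events, CueSchedule):
        events = events.events
    bin_times_s = np.asarray(bin_times_s, dtype=float)
    mids = bin_times_s - bin_s / 2.0
    labels = np.full(len(mids), rest_label, dtype=object)
    for ev in events:
        sel = (mids >= ev.onset_s - 1e-12) & (mids < ev.offset_s - 1e-12)
        labels[sel] = ev.label
    return labels


def mid_window_labels(
    schedule: CueSchedule,
    bin_times_s: np.ndarray,
    window_s: float = 1.0,
    bin_s: float = BIN_S,
) -> AlignedLabels:
    """Select the centered ``window_s`` bins of every cue (movement and rest).

    Cues shorter than the window are skipped with a warning.  The returned
    mask picks exactly ``window_s / bin_s`` bins per kept cue; labels
    outside the mask are excluded from mid-window datasets.
    """
    bin_times_s = np.asarray(bin_times_s, dtype=float)
    labels = rasterize(schedule, bin_times_s, bin_s)
    mask = np.zeros(len(bin_times_s), dtype=bool)
    n_sel = int(round(window_s / bin_s))
    mids = bin_times_s - bin_s / 2.0
    for ev in schedule.events:
        if ev.duration_s < window_s - 1e-9:
            log.warning("cue %s shorter than %gs window; skipped", ev.label, window_s)
            continue
        in_cue = np.nonzero((mids >= ev.onset_s - 1e-12) & (mids < ev.offset_s - 1e-12))[0]
        if len(in_cue) < n_sel:
            log.warning("cue %s covers fewer than %d bins; skipped", ev.label, n_sel)
            continue
        center = ev.midpoint_s
        # bins whose midpoints are nearest the cue midpoint, contiguous
        start = int(np.argmin(np.abs(mids[in_cue] - (center - window_s / 2 + bin_s / 2))))
        sel = in_cue[start : start + n_sel]
        if len(sel) < n_sel:  # clamp to the cue's trailing edge
            sel = in_cue[-n_sel:]
        mask[sel] = True
    return AlignedLabels(
        labels=labels,
        bin_times_s=bin_times_s,
        method="mid_window",
        events=list(schedule.events),
        mask=mask,
    )


def _shift_events(events: list[CueEvent], shift_s: float) -> list[CueEvent]:
    return [CueEvent(e.label, e.onset_s + shift_s, e.offset_s + shift_s) for e in events]


def static_shift(
    schedule: CueSchedule,
    shift_ms: float,
    bin_times_s: np.ndarray,
    bin_s: float = BIN_S,
) -> AlignedLabels:
    """Move every cue boundary later by ``shift_ms`` before rasterization.

    All events shift together, so ordering and durations are preserved;
    the final event is implicitly clipped to the recording end by the bin
    clock.
    """
    if shift_ms < 0:
        raise AlignmentError("static shift must be >= 0")
    events = _shift_events(schedule.events, shift_ms / 1000.0)
    labels = rasterize(events, bin_times_s, bin_s)
    n_mov = len(schedule.movement_events)
    return AlignedLabels(
        labels=labels,
        bin_times_s=np.asarray(bin_times_s, dtype=float),
        method=f"static({shift_ms:g}ms)",
        events=events,
        onset_shift_ms=np.full(n_mov, float(shift_ms)),
        offset_shift_ms=np.full(n_mov, float(shift_ms)),
    )


def _segment_sse(y: np.ndarray) -> float:
    """Residual sum of squares of the least-squares line through y."""
    n = len(y)
    if n < 2:
        return 0.0
    x = np.arange(n, dtype=float)
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.dot(xm, xm)
    slope = np.dot(xm, ym) / denom if denom > 0 else 0.0
    resid = ym - slope * xm
    return float(np.dot(resid, resid))


def two_segment_changepoint(y: np.ndarray, min_segment: int = 2) -> tuple[int, float]:
    """Best breakpoint of a two-segment piecewise-linear fit.

    Candidate k splits y into y[:k+1] and y[k:] (shared knot); the k
    minimizing total squared residuals is returned (ties -> earliest),
    together with that minimum.  This is the exhaustive sweep; windows are
    short (tens of bins), so O(n^2) is fine and doubles as its own oracle
    on noiseless input.
    """
    n = len(y)
    if n < 2 * min_segment:
        raise AlignmentError("window too short for the changepoint sweep")
    best_k, best_sse = -1, np.inf
    for k in range(min_segment - 1, n - min_segment + 1):
        sse = _segment_sse(y[: k + 1]) + _segment_sse(y[k:])
        if sse < best_sse - 1e-15:
            best_k, best_sse = k, sse
    return best_k, best_sse


def aggregate_rms(rms: np.ndarray) -> np.ndarray:
    """Mean over channels of per-channel z-scored RMS (gain-robust)."""
    mu = rms.mean(axis=0)
    sd = rms.std(axis=0) + 1e-12
    return ((rms - mu) / sd).mean(axis=1)


def _sweep_edge(
    agg: np.ndarray,
    bin_times_s: np.ndarray,
    edge_s: float,
    lo_s: float,
    hi_s: float,
    cfg: SweepConfig,
) -> float | None:
    """Relocate one cue edge; returns the new edge time or None if flat.

    Coarse-to-fine: the sweep over the full search window localizes the
    transition, then a second sweep within ``refine_halfwidth_ms`` of the
    coarse breakpoint pins the slope change without the surrounding
    steady-state segments dragging the fit.
    """
    half = cfg.search_window_ms / 1000.0
    lo = max(edge_s - half, lo_s)
    hi = min(edge_s + half, hi_s)
    mids = bin_times_s - BIN_S / 2.0
    idx = np.nonzero((mids >= lo) & (mids <= hi))[0]
    if len(idx) < 2 * cfg.min_segment_bins:
        return None
    if np.ptp(agg[idx]) < cfg.flat_tol:
        return None
    k_abs = idx[two_segment_changepoint(agg[idx], cfg.min_segment_bins)[0]]
    if cfg.refine_halfwidth_ms > 0:
        r = max(int(round(cfg.refine_halfwidth_ms / 1000.0 / BIN_S)), 2)
        sub = np.arange(max(idx[0], k_abs - r), min(idx[-1], k_abs + r) + 1)
        if len(sub) >= 2 * cfg.min_segment_bins and np.ptp(agg[sub]) >= cfg.flat_tol:
            k_abs = sub[two_segment_changepoint(agg[sub], cfg.min_segment_bins)[0]]
    return float(mids[k_abs])


def dynamic_shift(
    schedule: CueSchedule,
    rms: np.ndarray,
    bin_times_s: np.ndarray,
    cfg: SweepConfig | None = None,
) -> tuple[AlignedLabels, np.ndarray, np.ndarray]:
    """Minimum-residuals sweep alignment of every movement cue edge.

    For each cue onset (offset), aggregate RMS within a window around the
    edge — truncated at the midpoints of the neighboring events so windows
    never cross into the next cue — is fit with every possible two-segment
    line pair; the breakpoint with minimum total residual marks the
    steepest slope of the rising (falling) transition and becomes the new
    edge.  Reaction time is the signed difference to the original edge,
    floored at the anticipation allowance.  Windows with no slope fall
    back to the static default shift and are logged.

    Returns (labels, onset_reaction_ms, offset_reaction_ms) with one
    reaction time per movement event.
    """
    cfg = cfg or SweepConfig()
    bin_times_s = np.asarray(bin_times_s, dtype=float)
    agg = aggregate_rms(np.asarray(rms, dtype=float))
    events = list(schedule.events)
    move_idx = schedule.movement_indices
    onset_ms = np.zeros(len(move_idx))
    offset_ms = np.zeros(len(move_idx))
    new_events: list[CueEvent] = [CueEvent(e.label, e.onset_s, e.offset_s) for e in events]

    for k, ei in enumerate(move_idx):
        ev = events[ei]
        lo_on = events[ei - 1].midpoint_s if ei > 0 else 0.0
        hi_off = events[ei + 1].midpoint_s if ei + 1 < len(events) else bin_times_s[-1]
        new_on = _sweep_edge(agg, bin_times_s, ev.onset_s, lo_on, ev.midpoint_s, cfg)
        new_off = _sweep_edge(agg, bin_times_s, ev.offset_s, ev.midpoint_s, hi_off, cfg)
        if new_on is None:
            log.warning("flat RMS at onset of event %d; static fallback", ei)
            new_on = ev.onset_s + cfg.fallback_shift_ms / 1000.0
        if new_off is None:
            log.warning("flat RMS at offset of event %d; static fallback", ei)
            new_off = ev.offset_s + cfg.fallback_shift_ms / 1000.0
        floor = cfg.reaction_floor_ms / 1000.0
        new_on = max(new_on, ev.onset_s + floor)
        new_off = max(new_off, ev.offset_s + floor)
        if new_off <= new_on + BIN_S:  # never collapse the cue
            new_off = ev.offset_s
        onset_ms[k] = (new_on - ev.onset_s) * 1000.0
        offset_ms[k] = (new_off - ev.offset_s) * 1000.0
        new_events[ei] = CueEvent(ev.label, new_on, new_off)

    # keep the interleaved rests consistent with the moved cue edges
    for ei in move_idx:
        if ei > 0 and new_events[ei - 1].label == REST:
            r = new_events[ei - 1]
            new_events[ei - 1] = CueEvent(REST, min(r.onset_s, new_events[ei].onset_s), new_events[ei].onset_s)
        if ei + 1 < len(new_events) and new_events[ei + 1].label == REST:
            r = new_events[ei + 1]
            new_events[ei + 1] = CueEvent(
                REST, new_events[ei].offset_s, max(r.offset_s, new_events[ei].offset_s)
            )

    labels = rasterize(new_events, bin_times_s)
    aligned = AlignedLabels(
        labels=labels,
        bin_times_s=bin_times_s,
        method="dynamic",
        events=new_events,
        onset_shift_ms=onset_ms,
        offset_shift_ms=offset_ms,
    )
    return aligned, onset_ms, offset_ms
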