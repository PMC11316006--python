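"""Decoder evaluation metrics.

Bin-wise accuracy scores every 100 ms prediction against ground truth.
The per-cue *success rate* approximates an observer scoring each cue as a
binary outcome: a cue succeeds iff the decoder predicts the cued class
for (1) at least 5 consecutive bins (0.5 s) within the cue and (2) at
least 50% of the cue's bins.  *Decoder latency* is the time from a
per-event reference (shifted cue onset or measured EMG onset) to the
first correct prediction.  Regression quality is summarized by R2 and by
the median absolute error per joint in degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score

from .cue_align import BIN_S
from .errors import MetricError
from .simdata import REST, CueEvent, CueSchedule

log = logging.getLogger(__name__)

MIN_RUN_BINS = 5
MIN_CORRECT_FRAC = 0.5


@dataclass
class EventOutcome:
    label: str
    success: bool
    n_bins: int
    n_correct: int
    max_run: int


def binwise_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of bins whose predicted label matches ground truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise MetricError("prediction and truth lengths differ")
    if pred.size == 0:
        raise MetricError("bin-wise accuracy undefined on empty traces")
    return 100.0 * float(np.mean(pred == truth))


def _max_run(correct: np.ndarray) -> int:
    best = run = 0
    for c in correct:
        run = run + 1 if c else 0
        best = max(best, run)
    return best


def _event_bins(ev: CueEvent, bin_times_s: np.ndarray) -> np.ndarray:
    mids = bin_times_s - BIN_S / 2.0
    return np.nonzero((mids >= ev.onset_s - 1e-12) & (mids < ev.offset_s - 1e-12))[0]


def success_rate(
    pred: np.ndarray,
    events: list[CueEvent],
    bin_times_s: np.ndarray,
    min_run_bins: int = MIN_RUN_BINS,
    min_frac: float = MIN_CORRECT_FRAC,
) -> tuple[float, list[EventOutcome]]:
    """Two-criteria per-cue success over the given (possibly shifted) events.

    The 50%-of-duration criterion is inclusive (exactly half counts).
    Events spanning fewer than ``min_run_bins`` bins are excluded from
    the denominator and logged.
    """
    pred = np.asarray(pred)
    outcomes: list[EventOutcome] = []
    for ev in events:
        idx = _event_bins(ev, np.asarray(bin_times_s, dtype=float))
        if len(idx) < min_run_bins:
            log.warning("event %s spans %d bins; excluded", ev.label, len(idx))
            continue
        correct = pred[idx] == ev.label
        run = _max_run(correct)
        frac_ok = correct.sum() >= min_frac * len(idx)
        outcomes.append(
            EventOutcome(
                label=ev.label,
                success=bool(run >= min_run_bins and frac_ok),
                n_bins=len(idx),
                n_correct=int(correct.sum()),
                max_run=run,
            )
        )
    if not outcomes:
        raise MetricError("no scoreable events")
    rate = 100.0 * sum(o.success for o in outcomes) / len(outcomes)
    return rate, outcomes


def movements_only_success_rate(
    pred: np.ndarray,
    events: list[CueEvent],
    bin_times_s: np.ndarray,
    rest_label: str = REST,
) -> tuple[float, list[EventOutcome]]:
    """Success rate restricted to non-rest cues."""
    move_events = [e for e in events if e.label != rest_label]
    if not move_events:
        raise MetricError("no movement events to score")
    return success_rate(pred, move_events, bin_times_s)


def chance_levels(
    n_movements: int, schedule: CueSchedule, bin_times_s: np.ndarray
) -> tuple[float, float]:
    """(bin-wise chance %, movements-only chance %).

    Bin-wise chance is the accuracy of an always-rest decoder, i.e. the
    rest-bin fraction of the rasterized schedule (about 50% when rest of
    matched duration is interleaved between movements).  Movements-only
    chance is a uniform single guess over the movement classes.
    """
    if n_movements < 1:
        raise MetricError("n_movements must be >= 1")
    from .cue_align import rasterize

    labels = rasterize(schedule, bin_times_s)
    binwise = 100.0 * float(np.mean(labels == REST))
    return binwise, 100.0 / n_movements


def decoder_latency(
    pred: np.ndarray,
    events: list[CueEvent],
    references_s: np.ndarray,
    bin_times_s: np.ndarray,
    search_pre_s: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Latency (ms) from each event's reference time to its first correct bin.

    The search extent is [onset - search_pre_s, offset]; anticipatory
    correct bins give negative latency.  Events never predicted correctly
    within their extent are excluded from the distribution and counted in
    the summary.
    """
    bin_times_s = np.asarray(bin_times_s, dtype=float)
    mids = bin_times_s - BIN_S / 2.0
    lats: list[float] = []
    n_missed = 0
    for ev, ref in zip(events, references_s):
        if ref < bin_times_s[0] - BIN_S or ref > bin_times_s[-1]:
            log.warning("reference outside recording for %s; skipped", ev.label)
            continue
        sel = np.nonzero((mids >= ev.onset_s - search_pre_s) & (mids < ev.offset_s))[0]
        hit = sel[np.asarray(pred)[sel] == ev.label]
        if len(hit) == 0:
            n_missed += 1
            continue
        lats.append((bin_times_s[hit[0]] - ref) * 1000.0)
    lat = np.array(lats)
    summary = {
        "mean_ms": float(lat.mean()) if len(lat) else np.nan,
        "sem_ms": float(lat.std(ddof=1) / np.sqrt(len(lat))) if len(lat) > 1 else np.nan,
        "n": len(lat),
        "n_never_correct": n_missed,
    }
    return lat, summary


def regression_scores(
    pred: np.ndarray, truth: np.ndarray, joint_names: tuple[str, ...]
) -> dict:
    """R2 plus per-joint and grand median absolute error (degrees).

    R2 is reported both as the uniform average over joints and pooled
    over all joint-bin residuals; MAE is the median |error| per joint and
    the grand MAE the mean of the per-joint medians.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise MetricError("prediction and truth shapes differ")
    if np.any(truth.std(axis=0) == 0):
        raise MetricError("R2 undefined for zero-variance ground truth")
    err = np.abs(pred - truth)
    per_joint_mae = np.median(err, axis=0)
    return {
        "r2": float(r2_score(truth, pred, multioutput="uniform_average")),
        "r2_pooled": float(r2_score(truth.ravel(), pred.ravel())),
        "per_joint_mae_deg": dict(zip(joint_names, per_joint_mae.tolist())),
        "grand_mae_deg": float(per_joint_mae.mean()),
    }


def confusion(
    pred: np.ndarray,
    truth: np.ndarray,
    classes: list[str],
    events: list[CueEvent] | None = None,
    bin_times_s: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bin-count confusion matrix (rows = truth) with per-class accuracy.

    When events are supplied, a per-class success-rate column is appended
    as in per-movement decoder summaries.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    unknown = set(np.unique(truth)) | set(np.unique(pred))
    if not unknown <= set(classes):
        raise MetricError(f"labels outside class registry: {unknown - set(classes)}")
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth, pred):
        mat.loc[t, p] += 1
    counts = mat.sum(axis=1)
    acc = np.where(counts > 0, 100.0 * np.diag(mat.values) / np.maximum(counts, 1), np.nan)
    out = mat.copy()
    out["binwise_accuracy_pct"] = acc
    if events is not None and bin_times_s is not None:
        _, outcomes = success_rate(pred, events, bin_times_s)
        per_class: dict[str, list[bool]] = {}
        for o in outcomes:
            per_class.setdefault(o.label, []).append(o.success)
        out["success_rate_pct"] = [
            100.0 * np.mean(per_class[c]) if c in per_class else np.nan for c in classes
        ]
    return out


@dataclass
class EvalReport:
    """Bundle of the evaluation suite's outputs for one analysis."""

    binwise_accuracy_pct: float | None = None
    success_rate_pct: float | None = None
    movements_only_success_rate_pct: float | None = None
    chance_binwise_pct: float | None = None
    chance_movements_only_pct: float | None = None
    latency_summary: dict | None = None
    regression: dict | None = None
    confusion: pd.DataFrame | None = None
    extras: dict | None = None

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if v is not None and k != "confusion"
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion.to_dict()
        return d
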