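"""End-to-end experiment orchestration.

Ties the pipeline together: simulate a session, filter and bin the EMG,
stack lags, align labels, split attempts into train/validation/test the
way the recording paradigm prescribes (attempts 1-4 train, 5-7
validation, 8-10 test, validation merged into training once
hyperparameters are frozen), train the requested decoders over several
seeds, and evaluate.  Also provides the causal streaming loop that
replays a recording bin by bin through persisted filter state and checks
out identical to the offline path.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import sosfilt

from . import cue_align, evalmetrics, kinematics, models, sigproc, simdata
from .errors import ConfigurationError, ScheduleError, StreamingError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

TRAIN, VAL, TEST, UNUSED = "train", "val", "test", "unused"


@dataclass
class SplitPlan:
    """Per-event split assignment over a cue schedule."""

    assignment: np.ndarray  # len = n_events, dtype=object
    policy: str

    def event_indices(self, split: str) -> np.ndarray:
        return np.nonzero(self.assignment == split)[0]

    def bin_mask(
        self, schedule: simdata.CueSchedule, bin_times_s: np.ndarray, split: str
    ) -> np.ndarray:
        mids = np.asarray(bin_times_s, dtype=float) - cue_align.BIN_S / 2.0
        mask = np.zeros(len(mids), dtype=bool)
        for ei in self.event_indices(split):
            ev = schedule.events[ei]
            mask |= (mids >= ev.onset_s - 1e-12) & (mids < ev.offset_s - 1e-12)
        return mask


def build_splits(
    schedule: simdata.CueSchedule,
    policy: str = "sequential",
    train_attempts: int = 4,
    val_attempts: int = 3,
    test_attempts: int = 3,
    merge_val: bool = True,
    k_train: int | None = None,
) -> SplitPlan:
    """Deterministic attempt-index split of a sequential session.

    Per movement, the first ``train_attempts`` attempts train, the next
    ``val_attempts`` validate, the final ``test_attempts`` test; with
    ``merge_val`` the validation attempts fold into training (the
    post-freeze retraining convention).  ``k_train`` keeps only the first
    k attempts per movement in training (reduced-calibration sweeps).
    Each interleaved rest inherits the split of the following movement
    cue (the trailing rest that of the preceding cue).
    """
    need = train_attempts + val_attempts + test_attempts
    counts: dict[str, int] = {}
    assignment = np.array([UNUSED] * len(schedule.events), dtype=object)
    for ei, ev in enumerate(schedule.events):
        if ev.label == simdata.REST:
            continue
        counts[ev.label] = counts.get(ev.label, 0) + 1
        a = counts[ev.label]
        if a <= train_attempts + val_attempts:
            if k_train is not None:
                split = TRAIN if a <= k_train else UNUSED
            elif a <= train_attempts:
                split = TRAIN
            else:
                split = TRAIN if merge_val else VAL
        else:
            split = TEST
        assignment[ei] = split
    short = [m for m, c in counts.items() if c < need]
    if short:
        raise ScheduleError(
            f"movements with fewer than {need} attempts: {sorted(short)}"
        )
    # rests inherit the neighboring movement's split
    last = None
    for ei in range(len(schedule.events) - 1, -1, -1):
        if schedule.events[ei].label != simdata.REST:
            last = assignment[ei]
        elif last is not None:
            assignment[ei] = last
    for ei in range(len(schedule.events)):
        if schedule.events[ei].label != simdata.REST:
            break
        # leading rests already covered by the backward pass
    if assignment[-1] == UNUSED and len(schedule.events) > 1:
        assignment[-1] = assignment[-2]
    return SplitPlan(assignment=assignment, policy=policy)


# ---------------------------------------------------------------------------
# session preparation
# ---------------------------------------------------------------------------


@dataclass
class Session:
    """One simulated recording with its processed intermediates."""

    schedule: simdata.CueSchedule
    gestures: dict[str, simdata.GestureSpec]
    layout: simdata.SleeveLayout
    recording: simdata.EMGRecording
    glove: simdata.GloveTrack
    latencies: simdata.TrialLatencies
    rms: np.ndarray = field(default=None, repr=False)
    bin_times_s: np.ndarray = field(default=None, repr=False)
    features: sigproc.FeatureMatrix = field(default=None, repr=False)
    joints: kinematics.JointAngleTrack = field(default=None, repr=False)


def simulate_session(
    schedule: simdata.CueSchedule,
    gestures: dict[str, simdata.GestureSpec],
    layout: simdata.SleeveLayout,
    seed: int,
    snr: float = 10.0,
    reaction_model: tuple[float, float, float] = (500.0, 330.0, 100.0),
    filter_spec: sigproc.FilterSpec | None = None,
) -> Session:
    """Simulate a recording and run the standard front end over it."""
    rec, glove, lat = simdata.simulate_recording(
        schedule, gestures, layout, reaction_model=reaction_model, snr=snr, seed=seed
    )
    filtered = sigproc.filter_emg(rec, filter_spec)
    rms, bin_times = sigproc.compute_rms_bins(filtered)
    feats = sigproc.stack_lags(rms, bin_times)
    joints = kinematics.smooth_angles(
        kinematics.resample_to_bins(
            kinematics.derive_joint_angles(glove), bin_times
        )
    )
    return Session(
        schedule=schedule,
        gestures=gestures,
        layout=layout,
        recording=rec,
        glove=glove,
        latencies=lat,
        rms=rms,
        bin_times_s=bin_times,
        features=feats,
        joints=joints,
    )


def _aligned_labels(sess: Session, method: str) -> cue_align.AlignedLabels:
    if method == "none":
        labels = cue_align.rasterize(sess.schedule, sess.bin_times_s)
        return cue_align.AlignedLabels(
            labels=labels,
            bin_times_s=sess.bin_times_s,
            method="none",
            events=list(sess.schedule.events),
        )
    if method.startswith("static"):
        shift = float(method.removeprefix("static"))
        return cue_align.static_shift(sess.schedule, shift, sess.bin_times_s)
    if method == "dynamic":
        aligned, _, _ = cue_align.dynamic_shift(sess.schedule, sess.rms, sess.bin_times_s)
        return aligned
    raise ConfigurationError(f"unknown alignment method {method!r}")


def _seed_list(seeds) -> list[int]:
    if isinstance(seeds, int):
        return list(range(seeds))
    return list(seeds)


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------


def run_midwindow_classification(
    sess: Session,
    spec: models.ClassifierSpec,
    seeds=5,
    k_train: int | None = None,
) -> evalmetrics.EvalReport:
    """Mid-window (central 1 s per cue) classification, seed-averaged."""
    mid = cue_align.mid_window_labels(sess.schedule, sess.bin_times_s)
    plan = build_splits(sess.schedule, k_train=k_train)
    train_rows = mid.mask & plan.bin_mask(sess.schedule, sess.bin_times_s, TRAIN)
    test_rows = mid.mask & plan.bin_mask(sess.schedule, sess.bin_times_s, TEST)
    scaler = sigproc.fit_scaler(sess.features, train_rows)
    z = sigproc.apply_scaler(sess.features, scaler).values
    accs, preds = [], None
    for s in _seed_list(seeds):
        model = models.train_classifier(spec, z[train_rows], mid.labels[train_rows], s)
        preds = model.predict(z[test_rows])
        accs.append(evalmetrics.binwise_accuracy(preds, mid.labels[test_rows]))
    classes = sorted(set(mid.labels[test_rows]) | set(preds))
    return evalmetrics.EvalReport(
        binwise_accuracy_pct=float(np.mean(accs)),
        confusion=evalmetrics.confusion(preds, mid.labels[test_rows], classes),
        extras={"per_seed_accuracy_pct": accs, "n_test_bins": int(test_rows.sum())},
    )


def run_continuous_classification(
    sess: Session,
    spec: models.ClassifierSpec,
    seeds=5,
    alignment: str = "dynamic",
    k_train: int | None = None,
) -> evalmetrics.EvalReport:
    """Full time-series classification with the chosen cue alignment.

    Decoder latency is measured against the ground-truth muscle onset
    (cue onset plus the injected reaction delay) for test-set movement
    cues.
    """
    aligned = _aligned_labels(sess, alignment)
    plan = build_splits(sess.schedule, k_train=k_train)
    train_rows = plan.bin_mask(sess.schedule, sess.bin_times_s, TRAIN)
    test_rows = plan.bin_mask(sess.schedule, sess.bin_times_s, TEST)
    scaler = sigproc.fit_scaler(sess.features, train_rows)
    z = sigproc.apply_scaler(sess.features, scaler).values

    test_event_idx = [
        ei for ei in range(len(sess.schedule.events))
        if plan.assignment[ei] == TEST
    ]
    test_events = [aligned.events[ei] for ei in test_event_idx]
    move_rows = {int(ei): k for k, ei in enumerate(sess.latencies.event_indices)}
    move_test = [ei for ei in test_event_idx if sess.schedule.events[ei].label != simdata.REST]
    emg_onsets = np.array(
        [
            sess.schedule.events[ei].onset_s
            + sess.latencies.onset_delay_ms[move_rows[ei]] / 1000.0
            for ei in move_test
        ]
    )
    move_events = [aligned.events[ei] for ei in move_test]

    accs, succ, mo_succ, lat_means = [], [], [], []
    latencies = None
    for s in _seed_list(seeds):
        model = models.train_classifier(spec, z[train_rows], aligned.labels[train_rows], s)
        pred_full = np.full(len(sess.bin_times_s), simdata.REST, dtype=object)
        pred_full[test_rows] = model.predict(z[test_rows])
        accs.append(
            evalmetrics.binwise_accuracy(pred_full[test_rows], aligned.labels[test_rows])
        )
        sr, _ = evalmetrics.success_rate(pred_full, test_events, sess.bin_times_s)
        mr, _ = evalmetrics.movements_only_success_rate(
            pred_full, test_events, sess.bin_times_s
        )
        latencies, lsum = evalmetrics.decoder_latency(
            pred_full, move_events, emg_onsets, sess.bin_times_s
        )
        succ.append(sr)
        mo_succ.append(mr)
        if np.isfinite(lsum["mean_ms"]):
            lat_means.append(lsum["mean_ms"])
    chance_bin, chance_mo = evalmetrics.chance_levels(
        len(sess.schedule.labels), sess.schedule, sess.bin_times_s
    )
    return evalmetrics.EvalReport(
        binwise_accuracy_pct=float(np.mean(accs)),
        success_rate_pct=float(np.mean(succ)),
        movements_only_success_rate_pct=float(np.mean(mo_succ)),
        chance_binwise_pct=chance_bin,
        chance_movements_only_pct=chance_mo,
        latency_summary={
            "mean_ms": float(np.mean(lat_means)) if lat_means else np.nan,
            "per_seed_mean_ms": lat_means,
            "last_seed_latencies_ms": latencies.tolist() if latencies is not None else [],
        },
        extras={"per_seed_accuracy_pct": accs, "alignment": aligned.method},
    )


def run_regression(
    sess: Session,
    spec: models.RegressorSpec,
    seeds=5,
    exclude: tuple[str, ...] = kinematics.GROUP_EXCLUDED,
) -> evalmetrics.EvalReport:
    """Continuous joint-angle regression on the group (21-target) task."""
    joints = sess.joints.drop_joints(exclude) if exclude else sess.joints
    plan = build_splits(sess.schedule)
    train_rows = plan.bin_mask(sess.schedule, sess.bin_times_s, TRAIN)
    test_rows = plan.bin_mask(sess.schedule, sess.bin_times_s, TEST)
    scaler = sigproc.fit_scaler(sess.features, train_rows)
    z = sigproc.apply_scaler(sess.features, scaler).values
    y = joints.angles.T  # bins x joints
    r2s, maes, scores = [], [], None
    for s in _seed_list(seeds):
        model = models.train_regressor(
            spec, z[train_rows], y[train_rows], joints.joint_names, s
        )
        pred = model.predict(z[test_rows])
        scores = evalmetrics.regression_scores(pred, y[test_rows], joints.joint_names)
        r2s.append(scores["r2"])
        maes.append(scores["grand_mae_deg"])
        if spec.kind != "nn":
            break  # deterministic fits need no seed averaging
    return evalmetrics.EvalReport(
        regression={
            "r2": float(np.mean(r2s)),
            "grand_mae_deg": float(np.mean(maes)),
            "per_joint_mae_deg": scores["per_joint_mae_deg"],
            "per_seed_r2": r2s,
        }
    )


def run_cross_session_classification(
    train_sess: Session,
    test_sess: Session,
    spec: models.ClassifierSpec,
    seeds=5,
    mode: str = "mid_window",
    alignment: str = "dynamic",
) -> evalmetrics.EvalReport:
    """Mixed-test policy: train on one full session, test on another.

    The training session contributes every attempt (the sequential test
    attempts fold into training when the evaluation set is a separate
    mixed recording); movements absent from the test session's pool are
    dropped from training.  Labels come from mid-window masks or from the
    chosen alignment run independently per session.
    """
    pool = set(test_sess.schedule.labels) | {simdata.REST}
    if mode == "mid_window":
        tr = cue_align.mid_window_labels(train_sess.schedule, train_sess.bin_times_s)
        te = cue_align.mid_window_labels(test_sess.schedule, test_sess.bin_times_s)
        tr_rows = tr.mask & np.isin(tr.labels, list(pool))
        te_rows = te.mask
        y_tr, y_te = tr.labels, te.labels
    elif mode == "continuous":
        tr_al = _aligned_labels(train_sess, alignment)
        te_al = _aligned_labels(test_sess, alignment)
        tr_rows = np.isin(tr_al.labels, list(pool))
        te_rows = np.ones(len(te_al.labels), dtype=bool)
        y_tr, y_te = tr_al.labels, te_al.labels
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    scaler = sigproc.fit_scaler(train_sess.features, tr_rows)
    z_tr = sigproc.apply_scaler(train_sess.features, scaler).values
    z_te = sigproc.apply_scaler(test_sess.features, scaler).values
    accs, preds = [], None
    for s in _seed_list(seeds):
        model = models.train_classifier(spec, z_tr[tr_rows], y_tr[tr_rows], s)
        preds = model.predict(z_te[te_rows])
        accs.append(evalmetrics.binwise_accuracy(preds, y_te[te_rows]))
    chance_bin, chance_mo = evalmetrics.chance_levels(
        len(test_sess.schedule.labels), test_sess.schedule, test_sess.bin_times_s
    )
    return evalmetrics.EvalReport(
        binwise_accuracy_pct=float(np.mean(accs)),
        chance_binwise_pct=chance_bin,
        chance_movements_only_pct=chance_mo,
        extras={
            "per_seed_accuracy_pct": accs,
            "mode": mode,
            "dropped_movements": sorted(set(train_sess.schedule.labels) - pool),
        },
    )


def midwindow_training_rows(
    sess: Session, k_train: int | None = None, split: str = TRAIN
) -> tuple[np.ndarray, np.ndarray]:
    """Unstandardized mid-window feature rows + labels for one split."""
    mid = cue_align.mid_window_labels(sess.schedule, sess.bin_times_s)
    plan = build_splits(sess.schedule, k_train=k_train)
    rows = mid.mask & plan.bin_mask(sess.schedule, sess.bin_times_s, split)
    return sess.features.values[rows], mid.labels[rows]


def run_pretraining_comparison(
    cohort: list[Session],
    insession: Session,
    spec: models.ClassifierSpec,
    seeds=3,
    k_train: int = 1,
    target_layout: simdata.SleeveLayout | None = None,
) -> dict:
    """Fresh vs pretrained+fine-tuned mid-window accuracy at k in-session attempts.

    Cohort sessions are mapped to a common channel layout, pooled, and
    used to pretrain the network; fine-tuning sees only the first
    ``k_train`` attempts per movement of the in-session data, as does the
    fresh decoder.  Both are scored on the in-session test attempts.
    """
    def _mapped_feats(s: Session) -> np.ndarray:
        if target_layout is None or s.layout.size_tag == insession.layout.size_tag:
            return s.features.values
        rms = models.map_channels(s.rms, s.layout, target_layout)
        return sigproc.stack_lags(rms, s.bin_times_s).values

    pre_sets = []
    for s in cohort:
        mid = cue_align.mid_window_labels(s.schedule, s.bin_times_s)
        pre_sets.append((_mapped_feats(s)[mid.mask], mid.labels[mid.mask]))

    x_train, y_train = midwindow_training_rows(insession, k_train=k_train)
    x_test, y_test = midwindow_training_rows(insession, split=TEST)

    fresh_accs, pre_accs = [], []
    for s in _seed_list(seeds):
        scaler = models.fit_row_scaler(x_train)
        fresh = models.train_classifier(
            spec, models._scale_rows(x_train, scaler), y_train, s
        )
        fresh_accs.append(
            evalmetrics.binwise_accuracy(
                fresh.predict(models._scale_rows(x_test, scaler)), y_test
            )
        )
        bundle = models.pretrain_finetune(spec, pre_sets, (x_train, y_train), s)
        pre_accs.append(
            evalmetrics.binwise_accuracy(
                bundle.model.predict(models._scale_rows(x_test, bundle.scaler)), y_test
            )
        )
    return {
        "fresh_accuracy_pct": float(np.mean(fresh_accs)),
        "pretrained_accuracy_pct": float(np.mean(pre_accs)),
        "per_seed": {"fresh": fresh_accs, "pretrained": pre_accs},
        "k_train": k_train,
    }


# ---------------------------------------------------------------------------
# streaming inference
# ---------------------------------------------------------------------------


def stream_predict(
    model: models.FittedClassifier,
    scaler: sigproc.Scaler,
    rec: simdata.EMGRecording,
    filter_spec: sigproc.FilterSpec | None = None,
    chunk_ms: float = 100.0,
    n_lags: int = sigproc.DEFAULT_N_LAGS,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Causal bin-by-bin replay of a recording through the trained decoder.

    Each 100 ms chunk of raw EMG is filtered with persisted IIR state,
    reduced to an RMS row, pushed into the lag buffer (warmed up by
    replicating the first bin), standardized with the trained scaler, and
    classified.  The outputs match the offline pipeline on the same data.
    Returns (labels, probability rows, per-chunk log).
    """
    filter_spec = filter_spec or sigproc.FilterSpec()
    sos = filter_spec.design_sos(rec.fs_hz)
    n = int(round(rec.fs_hz * chunk_ms / 1000.0))
    if abs(rec.fs_hz * chunk_ms / 1000.0 - n) > 1e-9:
        raise StreamingError("chunk must be an integer number of samples")
    n_chunks = rec.signal.shape[1] // n
    zi = np.zeros((sos.shape[0], rec.signal.shape[0], 2))
    buffer: list[np.ndarray] = []
    labels, probs, chunk_log = [], [], []
    for c in range(n_chunks):
        t_start = time.perf_counter()
        chunk = rec.signal[:, c * n : (c + 1) * n].astype(np.float64)
        filtered, zi = sosfilt(sos, chunk, axis=1, zi=zi)
        rms_row = np.sqrt(np.mean(filtered**2, axis=1))
        if not buffer:
            buffer = [rms_row] * n_lags
        else:
            buffer = buffer[1:] + [rms_row]
        feat = np.concatenate(buffer)  # oldest first
        zrow = (feat - scaler.mean) / (scaler.sd + sigproc.SCALER_EPS)
        p = model.predict_proba(zrow[None, :])[0]
        labels.append(model.classes_[int(np.argmax(p))])
        probs.append(p)
        chunk_log.append(
            {"chunk": c, "n_samples": n, "elapsed_ms": (time.perf_counter() - t_start) * 1e3}
        )
    return np.array(labels, dtype=object), np.array(probs), chunk_log


# ---------------------------------------------------------------------------
# config-driven runner
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Serializable description of one experiment run."""

    paradigm: str = "sequential"
    n_movements: int = 12
    mixed_pool_size: int | None = None  # movements kept in the mixed test set
    reps: int = 10
    n_channels: int = 20
    layout_tag: str = "custom"
    snr: float = 10.0
    reaction_model: tuple[float, float, float] = (500.0, 330.0, 100.0)
    classifier_kind: str = "nn"
    regressor_kind: str = "nn"
    alignment: str = "dynamic"
    epochs: int = 20
    finetune_epochs: int = 5
    seeds: int = 5
    k_train: int | None = None
    analyses: tuple[str, ...] = ("mid_window", "continuous", "regression")
    sim_seed: int = 0

    def to_yaml(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        return yaml.safe_dump(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def classifier_spec(self) -> models.ClassifierSpec:
        return models.ClassifierSpec(
            kind=self.classifier_kind,
            epochs=self.epochs,
            finetune_epochs=self.finetune_epochs,
        )

    def regressor_spec(self) -> models.RegressorSpec:
        return models.RegressorSpec(kind=self.regressor_kind, epochs=self.epochs)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Simulate one session and run the requested analyses.

    Returns a report dict whose manifest names the config hash and seed
    list, so a config + seed reproduces the run at the metric level.
    """
    movements = [f"M{i:02d}" for i in range(cfg.n_movements)]
    layout = (
        simdata.SleeveLayout.from_size(cfg.layout_tag)
        if cfg.layout_tag in simdata.SLEEVE_SIZES
        else simdata.SleeveLayout.custom(cfg.n_channels)
    )
    gestures = simdata.make_gesture_set(movements, layout, seed=cfg.sim_seed)
    schedule = simdata.make_sequential_schedule(movements, reps=cfg.reps, seed=cfg.sim_seed)
    sess = simulate_session(
        schedule, gestures, layout,
        seed=cfg.sim_seed, snr=cfg.snr, reaction_model=cfg.reaction_model,
    )
    report: dict = {
        "manifest": {
            "config_hash": cfg.config_hash,
            "seeds": _seed_list(cfg.seeds),
            "config": yaml.safe_load(cfg.to_yaml()),
        }
    }
    if cfg.paradigm == "mixed":
        # mixed-test policy: the full sequential session trains, a separate
        # mixed-block session tests; movements outside the pool are dropped
        pool = movements[: cfg.mixed_pool_size] if cfg.mixed_pool_size else movements
        mix_schedule = simdata.make_mixed_schedule(pool, seed=cfg.sim_seed + 1)
        test_sess = simulate_session(
            mix_schedule, gestures, layout,
            seed=cfg.sim_seed + 1, snr=cfg.snr, reaction_model=cfg.reaction_model,
        )
        for mode in ("mid_window", "continuous"):
            if mode in cfg.analyses:
                rep = run_cross_session_classification(
                    sess, test_sess, cfg.classifier_spec(), seeds=cfg.seeds,
                    mode=mode, alignment=cfg.alignment,
                )
                report[mode] = rep.to_dict()
        return report
    if "mid_window" in cfg.analyses:
        rep = run_midwindow_classification(
            sess, cfg.classifier_spec(), seeds=cfg.seeds, k_train=cfg.k_train
        )
        report["mid_window"] = rep.to_dict()
    if "continuous" in cfg.analyses:
        rep = run_continuous_classification(
            sess, cfg.classifier_spec(), seeds=cfg.seeds,
            alignment=cfg.alignment, k_train=cfg.k_train,
        )
        report["continuous"] = rep.to_dict()
    if "regression" in cfg.analyses:
        rep = run_regression(sess, cfg.regressor_spec(), seeds=cfg.seeds)
        report["regression"] = rep.to_dict()
    return report
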