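"""Splits, end-to-end runner, streaming equivalence, session containers."""

import numpy as np
import pytest

from emgsleeve import cue_align, evalmetrics, io as session_io, models, orchestrate, sigproc, simdata
from emgsleeve.errors import ScheduleError
from emgsleeve.orchestrate import TEST, TRAIN, UNUSED, VAL, build_splits


class TestBuildSplits:
    def _schedule(self, reps=10, movements=("a", "b")):
        return simdata.make_sequential_schedule(list(movements), reps=reps, seed=0)

    def test_four_three_three_with_merge(self):
        sch = self._schedule()
        plan = build_splits(sch)
        per_move = {}
        for ei, ev in enumerate(sch.events):
            if ev.label != simdata.REST:
                per_move.setdefault(ev.label, []).append(plan.assignment[ei])
        for splits in per_move.values():
            assert splits.count(TRAIN) == 7  # 4 train + 3 merged validation
            assert splits.count(TEST) == 3

    def test_unmerged_validation(self):
        sch = self._schedule()
        plan = build_splits(sch, merge_val=False)
        labels = [
            plan.assignment[ei]
            for ei, ev in enumerate(sch.events)
            if ev.label == "a"
        ]
        assert labels == [TRAIN] * 4 + [VAL] * 3 + [TEST] * 3

    def test_reduced_training_keeps_first_k(self):
        sch = self._schedule()
        plan = build_splits(sch, k_train=1)
        labels = [
            plan.assignment[ei] for ei, ev in enumerate(sch.events) if ev.label == "a"
        ]
        assert labels == [TRAIN] + [UNUSED] * 6 + [TEST] * 3

    def test_no_event_in_two_splits(self):
        plan = build_splits(self._schedule())
        assert set(plan.assignment) <= {TRAIN, VAL, TEST, UNUSED}

    def test_insufficient_attempts_names_movement(self):
        with pytest.raises(ScheduleError, match="a"):
            build_splits(self._schedule(reps=5))

    def test_train_test_bins_disjoint(self):
        sch = self._schedule()
        bins = np.arange(1, int(sch.end_s * 10) + 1) * 0.1
        plan = build_splits(sch)
        tr = plan.bin_mask(sch, bins, TRAIN)
        te = plan.bin_mask(sch, bins, TEST)
        assert not np.any(tr & te)


@pytest.fixture(scope="module")
def decoder(small_session):
    sess = small_session
    mid = cue_align.mid_window_labels(sess.schedule, sess.bin_times_s)
    scaler = sigproc.fit_scaler(sess.features, mid.mask)
    z = sigproc.apply_scaler(sess.features, scaler).values
    spec = models.ClassifierSpec(epochs=5)
    model = models.train_classifier(spec, z[mid.mask], mid.labels[mid.mask], seed=0)
    return model, scaler


class TestStreaming:
    def test_stream_equals_offline(self, small_session, decoder):
        model, scaler = decoder
        sess = small_session
        labels, probs, logrows = orchestrate.stream_predict(
            model, scaler, sess.recording
        )
        z = sigproc.apply_scaler(sess.features, scaler).values
        offline_probs = model.predict_proba(z)
        offline_labels = model.classes_[offline_probs.argmax(axis=1)]
        assert len(labels) == len(offline_labels)
        assert np.max(np.abs(probs - offline_probs)) <= 1e-6
        assert np.array_equal(labels, offline_labels)

    def test_warmup_chunks_defined_and_normalized(self, small_session, decoder):
        model, scaler = decoder
        short = simdata.EMGRecording(
            signal=small_session.recording.signal[:, : 300 * 6],
            fs_hz=small_session.recording.fs_hz,
            layout=small_session.layout,
        )
        labels, probs, logrows = orchestrate.stream_predict(model, scaler, short)
        assert len(labels) == 6
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert len(logrows) == 6


class TestRunExperiment:
    CFG = dict(
        n_movements=3, reps=10, n_channels=6, epochs=3, seeds=1,
        analyses=("mid_window",), sim_seed=5,
    )

    def test_deterministic_and_manifested(self):
        r1 = orchestrate.run_experiment(orchestrate.ExperimentConfig(**self.CFG))
        r2 = orchestrate.run_experiment(orchestrate.ExperimentConfig(**self.CFG))
        assert r1["mid_window"]["binwise_accuracy_pct"] == r2["mid_window"]["binwise_accuracy_pct"]
        assert r1["manifest"]["config_hash"] == r2["manifest"]["config_hash"]
        assert r1["manifest"]["seeds"] == [0]

    def test_unknown_alignment_rejected(self, small_session):
        with pytest.raises(Exception):
            orchestrate.run_continuous_classification(
                small_session, models.ClassifierSpec(epochs=1), seeds=1, alignment="bogus"
            )


class TestSequentialVsMixedGeneralization:
    def test_within_paradigm_accuracy_not_worse(self, small_session, small_gestures, small_layout):
        """Decoders generalize worse to a mixed session with slower reactions."""
        sess = small_session
        aligned, _, _ = cue_align.dynamic_shift(sess.schedule, sess.rms, sess.bin_times_s)
        plan = build_splits(sess.schedule)
        tr = plan.bin_mask(sess.schedule, sess.bin_times_s, TRAIN)
        te = plan.bin_mask(sess.schedule, sess.bin_times_s, TEST)
        scaler = sigproc.fit_scaler(sess.features, tr)
        z = sigproc.apply_scaler(sess.features, scaler).values
        model = models.train_classifier(
            models.ClassifierSpec(epochs=10), z[tr], aligned.labels[tr], seed=0
        )
        seq_acc = evalmetrics.binwise_accuracy(model.predict(z[te]), aligned.labels[te])

        mixed_schedule = simdata.make_mixed_schedule(
            list(small_session.schedule.labels), seed=21
        )
        mixed = orchestrate.simulate_session(
            mixed_schedule, small_gestures, small_layout, seed=22, snr=10.0,
            reaction_model=(585.0, 290.0, 100.0),
        )
        m_aligned, _, _ = cue_align.dynamic_shift(
            mixed.schedule, mixed.rms, mixed.bin_times_s
        )
        zm = sigproc.apply_scaler(mixed.features, scaler).values
        mixed_acc = evalmetrics.binwise_accuracy(model.predict(zm), m_aligned.labels)
        assert seq_acc >= mixed_acc


class TestMixedTestPolicy:
    def test_out_of_pool_movements_dropped(self):
        cfg = orchestrate.ExperimentConfig(
            paradigm="mixed", n_movements=4, mixed_pool_size=3, reps=10,
            n_channels=6, epochs=5, seeds=1, analyses=("mid_window",), sim_seed=9,
        )
        report = orchestrate.run_experiment(cfg)
        mw = report["mid_window"]
        assert mw["extras"]["dropped_movements"] == ["M03"]
        assert mw["binwise_accuracy_pct"] > mw["chance_binwise_pct"]


class TestSessionContainer:
    def test_hdf5_round_trip(self, tmp_path, small_layout, small_gestures):
        schedule = simdata.make_sequential_schedule(["Grasp"], reps=2, seed=1)
        rec, glove, lat = simdata.simulate_recording(
            schedule, small_gestures, small_layout, seed=1
        )
        path = tmp_path / "session.h5"
        session_io.save_session(path, rec, glove, schedule, lat)
        rec2, glove2, schedule2, lat2 = session_io.load_session(path)
        assert np.array_equal(rec.signal, rec2.signal)
        assert np.array_equal(glove.sensors, glove2.sensors)
        assert schedule2.events == schedule.events
        assert np.array_equal(lat.onset_delay_ms, lat2.onset_delay_ms)
        assert rec2.layout.n_channels == rec.layout.n_channels

    def test_cues_csv(self, tmp_path):
        import pandas as pd

        schedule = simdata.make_sequential_schedule(["a", "b"], reps=2, seed=0)
        path = tmp_path / "cues.csv"
        session_io.export_cues_csv(path, schedule)
        df = pd.read_csv(path)
        assert len(df) == len(schedule.events)
        assert set(df.columns) >= {"label", "onset_s", "offset_s", "block", "paradigm"}


class TestCli:
    def test_generate_and_cues(self, tmp_path):
        from click.testing import CliRunner

        from emgsleeve.cli import main

        runner = CliRunner()
        out = tmp_path / "s.h5"
        res = runner.invoke(
            main,
            ["generate", "--movements", "2", "--reps", "2", "--channels", "5",
             "--seed", "1", "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        assert out.exists()
        res = runner.invoke(
            main, ["cues", "--movements", "3", "--seed", "1", "--out", str(tmp_path / "c.csv")]
        )
        assert res.exit_code == 0, res.output
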