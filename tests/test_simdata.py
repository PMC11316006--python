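"""Generator contracts: schedules, spectra, label-signal coupling, kinematics."""

import numpy as np
import pytest
from scipy import signal as sps

from emgsleeve import simdata
from emgsleeve.errors import ConfigurationError, ScheduleError
from emgsleeve.simdata import (
    REST,
    SleeveLayout,
    make_gesture_set,
    make_mixed_schedule,
    make_sequential_schedule,
    simulate_recording,
)


class TestLayouts:
    @pytest.mark.parametrize("tag,n", [("small", 59), ("medium", 70), ("large", 75)])
    def test_named_sizes(self, tag, n):
        lay = SleeveLayout.from_size(tag)
        assert lay.n_channels == n
        assert lay.grid_coords.shape == (n, 2)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            SleeveLayout("small", 60, np.zeros((60, 2)))

    def test_duplicate_coords_rejected(self):
        coords = np.zeros((5, 2))
        with pytest.raises(ConfigurationError):
            SleeveLayout("custom", 5, coords)


class TestSequentialSchedule:
    def test_full_paradigm_counts(self):
        movements = [f"M{i}" for i in range(37)]
        sch = make_sequential_schedule(movements, reps=10, seed=3)
        moves = sch.movement_events
        rests = [e for e in sch.events if e.label == REST]
        assert len(moves) == 370
        assert len(rests) >= 370
        assert sch.paradigm == "sequential"
        # attempts of one movement are consecutive (blocked)
        labels = [e.label for e in moves]
        assert labels == sorted(labels, key=movements.index)

    def test_minimal_case(self):
        sch = make_sequential_schedule(["only"], reps=1, seed=0)
        assert len(sch.movement_events) == 1

    def test_durations_within_range(self):
        sch = make_sequential_schedule(["a", "b"], reps=5, seed=1)
        for e in sch.events:
            assert 2.0 <= e.duration_s <= 3.0

    def test_deterministic(self):
        a = make_sequential_schedule(["a", "b"], reps=3, seed=9)
        b = make_sequential_schedule(["a", "b"], reps=3, seed=9)
        assert a.events == b.events

    def test_empty_movements_rejected(self):
        with pytest.raises(ScheduleError):
            make_sequential_schedule([], reps=10)


class TestMixedSchedule:
    def test_pool_coverage_and_block_sizes(self):
        pool = [f"G{i}" for i in range(19)]
        sch = make_mixed_schedule(pool, reps_per_movement=5, seed=5)
        moves = sch.movement_events
        assert {e.label for e in moves} == set(pool)
        blocks = {}
        for e, b in zip(sch.events, sch.block_ids):
            if e.label != REST:
                blocks.setdefault(b, []).append(e.label)
        for members in blocks.values():
            assert 3 <= len(set(members)) <= 6
            for lab in set(members):
                assert members.count(lab) == 5

    def test_fixed_block_of_three(self):
        sch = make_mixed_schedule(["x", "y", "z"], movements_per_block=(3, 3), seed=2)
        assert len(sch.movement_events) == 15
        assert len(set(sch.block_ids)) == 1

    def test_no_adjacent_repeats(self):
        sch = make_mixed_schedule([f"G{i}" for i in range(6)], seed=8)
        labs = [e.label for e in sch.movement_events]
        assert all(a != b for a, b in zip(labs, labs[1:]))

    def test_deterministic(self):
        pool = [f"G{i}" for i in range(7)]
        assert make_mixed_schedule(pool, seed=4).events == make_mixed_schedule(pool, seed=4).events

    def test_zero_reps_rejected(self):
        with pytest.raises(ScheduleError):
            make_mixed_schedule(["a", "b", "c"], reps_per_movement=0)


class TestGestureSets:
    def test_maps_distinct_but_confusable(self, small_layout):
        specs = make_gesture_set([f"M{i}" for i in range(6)], small_layout, seed=0)
        maps = [s.activation_map for k, s in specs.items() if k != REST]
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                assert abs(np.corrcoef(maps[i], maps[j])[0, 1]) < 0.9

    def test_rest_spec_is_silent(self, small_layout):
        specs = make_gesture_set(["a"], small_layout, seed=0)
        assert not np.any(specs[REST].activation_map > 0)


@pytest.fixture(scope="module")
def tiny(small_layout):
    gestures = make_gesture_set(["a", "b"], small_layout, seed=1)
    schedule = make_sequential_schedule(["a", "b"], reps=3, seed=1)
    return schedule, gestures, small_layout


class TestSimulateRecording:
    def test_deterministic(self, tiny):
        out1 = simulate_recording(*tiny, seed=42)
        out2 = simulate_recording(*tiny, seed=42)
        assert np.array_equal(out1[0].signal, out2[0].signal)
        assert np.array_equal(out1[1].sensors, out2[1].sensors)
        assert np.array_equal(out1[2].onset_delay_ms, out2[2].onset_delay_ms)

    def test_zero_variance_reaction_model(self, tiny):
        _, _, lat = simulate_recording(*tiny, reaction_model=(400.0, 300.0, 0.0), seed=0)
        assert np.all(lat.onset_delay_ms == 400.0)
        assert np.all(lat.offset_delay_ms == 300.0)

    def test_cue_amplitude_exceeds_rest_on_active_channels(self, tiny):
        schedule, gestures, layout = tiny
        rec, _, lat = simulate_recording(
            schedule, gestures, layout, snr=100.0, reaction_model=(0, 0, 0), seed=2
        )
        fs = rec.fs_hz
        for k, ei in enumerate(lat.event_indices):
            ev = schedule.events[ei]
            act = gestures[ev.label].activation_map
            mid = np.abs(
                rec.signal[:, int((ev.onset_s + 0.5) * fs) : int((ev.offset_s - 0.5) * fs)]
            ).mean(axis=1)
            pre = np.abs(
                rec.signal[:, int((ev.onset_s - 1.5) * fs) : int((ev.onset_s - 0.5) * fs)]
            ).mean(axis=1)
            assert np.all(mid[act > 0.05] > pre[act > 0.05])

    def test_rest_only_schedule_is_baseline_noise(self, small_layout):
        gestures = make_gesture_set(["a"], small_layout, seed=1)
        schedule = simdata.CueSchedule(
            events=[simdata.CueEvent(REST, 0.0, 10.0)], paradigm="sequential"
        )
        rec, _, _ = simulate_recording(schedule, gestures, small_layout, snr=1.0, seed=3)
        power = (rec.signal.astype(float) ** 2).mean(axis=1)
        assert np.all(np.abs(power - 1.0) < 0.15)  # baseline_rms=1, small line term

    def test_spectral_contract(self, tiny):
        schedule, gestures, layout = tiny
        rec, _, _ = simulate_recording(schedule, gestures, layout, snr=10.0, seed=4)
        f, pxx = sps.welch(rec.signal[0].astype(float), fs=rec.fs_hz, nperseg=4096)
        line = (f > 55) & (f < 65)
        in_band = (f >= 20) & (f <= 400) & ~line
        out_band = ~((f >= 20) & (f <= 400)) & ~line
        assert pxx[out_band].sum() < 0.05 * pxx[in_band].sum()

    def test_snr_monotone_margin(self, tiny):
        schedule, gestures, layout = tiny
        margins = []
        for snr in (10.0, 30.0):
            rec, _, lat = simulate_recording(
                schedule, gestures, layout, snr=snr, reaction_model=(0, 0, 0), seed=5
            )
            fs = rec.fs_hz
            ev = schedule.movement_events[0]
            ch = int(np.argmax(gestures[ev.label].activation_map))
            cue = rec.signal[ch, int((ev.onset_s + 0.5) * fs) : int((ev.offset_s - 0.5) * fs)]
            rest = rec.signal[ch, int((ev.onset_s - 1.5) * fs) : int((ev.onset_s - 0.5) * fs)]
            margins.append(np.sqrt((cue.astype(float) ** 2).mean())
                           / np.sqrt((rest.astype(float) ** 2).mean()))
        assert margins[1] > margins[0] > 1.0

    def test_glove_reaches_target_pose(self, tiny):
        from emgsleeve import kinematics as kin

        schedule, gestures, layout = tiny
        _, glove, _ = simulate_recording(
            schedule, gestures, layout, reaction_model=(0, 0, 0), seed=6,
            sensor_noise_sd_deg=0.2,
        )
        ev = schedule.movement_events[0]
        spec = gestures[ev.label]
        sel = slice(int((ev.onset_s + 1.0) * glove.fs_hz), int((ev.offset_s - 0.2) * glove.fs_hz))
        direct = [kin.JOINT_NAMES.index(n) for n in kin.DIRECT_JOINTS]
        steady = glove.sensors[:, sel].mean(axis=1)
        assert np.allclose(steady, spec.target_pose[direct], atol=3 * 0.2)

    def test_missing_gesture_spec_rejected(self, tiny):
        schedule, gestures, layout = tiny
        bad = {k: v for k, v in gestures.items() if k != "b"}
        with pytest.raises(ConfigurationError):
            simulate_recording(schedule, bad, layout, seed=0)
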