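"""Trial assembly, locomotion segmentation, speed integration and container I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import optovis as ov
from optovis.session import SchemaError, _locomotion_state


class TestIntegrateSpeed:
    def test_single_event_definition(self):
        tr = ov.integrate_speed([0.05], [0.2], bin_length=0.1, duration=0.1)
        assert tr.v[0] == pytest.approx(2.0)

    def test_empty_stream_gives_zero_trace(self):
        tr = ov.integrate_speed([], [], bin_length=0.1, duration=1.0)
        assert tr.v.shape == (10,)
        assert np.all(tr.v == 0)

    def test_multiple_events_sum_within_bin(self):
        times = 0.3 + np.linspace(0.005, 0.095, 5)
        disp = np.full(5, 0.3)  # 1.5 cm total inside bin 3
        tr = ov.integrate_speed(times, disp, bin_length=0.1, duration=1.0)
        assert tr.v[3] == pytest.approx(15.0)
        assert tr.v[[0, 1, 2, 4]].sum() == 0

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 9.99, allow_nan=False),
                st.floats(0, 1.0, allow_nan=False),
            ),
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_total_displacement_conserved(self, events):
        events.sort()
        t = [e[0] for e in events]
        d = [e[1] for e in events]
        tr = ov.integrate_speed(t, d, bin_length=0.1, duration=10.0)
        assert tr.v.sum() * 0.1 == pytest.approx(sum(d), abs=1e-9)


class TestClassifyLocomotion:
    def _trace(self, value, duration=10.0):
        t = np.arange(0.05, duration, 0.1)
        return ov.SpeedTrace(t=t, v=np.full_like(t, value))

    @pytest.mark.parametrize(
        "speed,threshold,expected",
        [(5.0, 3.0, "running"), (0.0, 2.0, "still"), (2.0, 2.0, "still")],
    )
    def test_threshold_rule_is_strict(self, speed, threshold, expected):
        cfg = ov.LocomotionConfig(speed_threshold=threshold)
        assert ov.classify_locomotion((1.0, 3.0), self._trace(speed), cfg) == expected

    def test_span_outside_trace_errors(self):
        with pytest.raises(ValueError, match="misaligned"):
            ov.classify_locomotion((8.0, 12.0), self._trace(1.0), ov.LocomotionConfig())

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.05, 10, 0.1)
        tr = ov.SpeedTrace(t=t, v=rng.uniform(0, 10, t.size))
        states = [
            ov.classify_locomotion(
                (2.0, 4.0), tr, ov.LocomotionConfig(speed_threshold=th)
            )
            for th in np.linspace(0.5, 12, 24)
        ]
        # once still, raising the threshold can never flip back to running
        first_still = states.index("still") if "still" in states else len(states)
        assert all(s == "still" for s in states[first_still:])


class TestBuildTrials:
    def test_half_open_counting_window(self, make_session):
        sess = make_session([[0.6, 1.4, 1.6]], [(0.0, 2.0, 0.0), (10.0, 2.0, 90.0)])
        table = ov.build_trials(sess)
        assert table.counts[0, 0] == 2  # 1.6 excluded by [0.5, 1.5)
        assert table.counts[1, 0] == 0

    def test_full_schedule_row_count(self, small_session, small_cfg):
        sess, _ = small_session
        table = ov.build_trials(sess)
        expected = small_cfg.n_directions * small_cfg.n_repeats * 2
        assert table.n_trials == expected
        assert table.laser_on.sum() == expected // 2

    def test_silent_unit_gives_zero_column(self, make_session):
        sess = make_session([[0.6], []], [(0.0, 2.0, 0.0), (5.0, 2.0, 45.0)])
        table = ov.build_trials(sess)
        assert np.all(table.counts[:, 1] == 0)

    def test_window_beyond_stimulus_errors(self, make_session):
        sess = make_session([[0.6]], [(0.0, 1.0, 0.0)])
        with pytest.raises(ValueError, match="onset 0"):
            ov.build_trials(sess, window_start_offset=0.5, window_length=1.0)

    def test_total_spike_mass_bounded(self, small_session):
        sess, _ = small_session
        table = ov.build_trials(sess)
        total_spikes = sum(u.spike_times.size for u in sess.units)
        assert table.counts.sum() <= total_spikes

    def test_time_translation_invariance(self, make_session):
        spikes = [[0.6, 1.2, 5.7, 6.2], [0.8, 6.1]]
        stims = [(0.0, 2.0, 0.0), (5.0, 2.0, 180.0)]
        lasers = [(5.0, 2.0)]
        shift = 7.3
        a = ov.build_trials(make_session(spikes, stims, lasers))
        b = ov.build_trials(
            make_session(
                [[t + shift for t in s] for s in spikes],
                [(o + shift, d, dd) for o, d, dd in stims],
                [(o + shift, d) for o, d in lasers],
            )
        )
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.laser_on, b.laser_on)
        assert np.array_equal(a.stimulus_direction, b.stimulus_direction)

    def test_laser_flag_from_overlap(self, make_session):
        sess = make_session(
            [[0.6]], [(0.0, 2.0, 0.0), (5.0, 2.0, 0.0)], laser_specs=[(5.0, 2.0)]
        )
        table = ov.build_trials(sess)
        assert list(table.laser_on) == [False, True]


class TestSessionIO:
    def test_round_trip_identity(self, small_session, tmp_path):
        sess, _ = small_session
        path = tmp_path / "s.h5"
        ov.write_session(sess, path)
        back = ov.read_session(path)
        assert back.subject_id == sess.subject_id
        assert back.region == sess.region and back.opsin == sess.opsin
        assert np.array_equal(back.lfp, sess.lfp)
        assert back.lfp_rate == sess.lfp_rate
        assert np.array_equal(back.channel_depths, sess.channel_depths)
        assert len(back.units) == len(sess.units)
        orig = {u.unit_id: u for u in sess.units}
        for u in back.units:
            o = orig[u.unit_id]
            assert np.array_equal(u.spike_times, o.spike_times)
            assert np.array_equal(u.mean_waveform, o.mean_waveform)
            assert u.sort_class == o.sort_class
            assert u.channel_index == o.channel_index
        assert np.array_equal(back.speed.t, sess.speed.t)
        assert np.array_equal(back.speed.v, sess.speed.v)
        assert len(back.stimulus_events) == len(sess.stimulus_events)
        for be, oe in zip(back.stimulus_events, sess.stimulus_events):
            assert (be.onset, be.duration, be.kind, be.direction) == (
                oe.onset, oe.duration, oe.kind, oe.direction,
            )
        assert len(back.laser_events) == len(sess.laser_events)

    def test_missing_field_names_it(self, small_session, tmp_path):
        import h5py

        sess, _ = small_session
        path = tmp_path / "s.h5"
        ov.write_session(sess, path)
        with h5py.File(path, "a") as f:
            del f["lfp/depths"]
        with pytest.raises(SchemaError, match="depths"):
            ov.read_session(path)

    def test_empty_units_round_trip(self, make_session, tmp_path):
        sess = make_session([], [(0.0, 2.0, 0.0), (5.0, 2.0, 90.0)])
        path = tmp_path / "empty.h5"
        ov.write_session(sess, path)
        back = ov.read_session(path)
        table = ov.build_trials(back)
        assert table.counts.shape == (2, 0)


class TestTrialTableCsv:
    def test_round_trip(self, small_table, tmp_path):
        path = tmp_path / "trials.csv"
        small_table.to_csv(path)
        back = ov.TrialTable.from_csv(path)
        assert np.array_equal(back.counts, small_table.counts)
        assert back.unit_ids == small_table.unit_ids
        assert np.array_equal(back.laser_on, small_table.laser_on)
        assert back.window_length == small_table.window_length
        assert back.window_start_offset == small_table.window_start_offset


class TestInvariants:
    def test_speed_trace_rejects_negative(self):
        with pytest.raises(ValueError):
            ov.SpeedTrace(t=np.array([0.05, 0.15]), v=np.array([1.0, -0.1]))

    def test_laser_events_must_not_overlap(self, make_session):
        with pytest.raises(ValueError, match="overlap"):
            make_session([[0.6]], [(0.0, 2.0, 0.0)],
                         laser_specs=[(0.0, 2.0), (1.0, 2.0)])

    def test_lfp_rate_must_clear_analysis_band(self):
        with pytest.raises(ValueError, match="lfp_rate"):
            ov.Session(
                subject_id="x", region="V1", opsin="ChR2",
                lfp=np.zeros((1, 100)), lfp_rate=500.0,
                channel_depths=np.array([100.0]),
                channel_shanks=np.array([0]),
                units=[], speed=ov.SpeedTrace(t=np.array([0.05]), v=np.array([0.0])),
                stimulus_events=[], laser_events=[],
            )
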