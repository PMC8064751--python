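import dataclasses

import numpy as np
import pytest

import optovis as ov


@pytest.fixture(scope="session")
def small_cfg():
    """Small grating session: quick to generate, full schedule structure."""
    return ov.GeneratorConfig(
        n_units_bs=6, n_units_ns=3, n_repeats=5, n_channels=2, seed=11
    )


@pytest.fixture(scope="session")
def small_session(small_cfg):
    sess, truth = ov.generate_session(small_cfg)
    return sess, truth


@pytest.fixture(scope="session")
def small_table(small_session):
    sess, _ = small_session
    return ov.build_trials(sess)


@pytest.fixture(scope="session")
def recovery_session():
    """Full-schedule session at default study conditions (160 trials per
    laser condition), used for parameter-recovery checks."""
    cfg = ov.GeneratorConfig(n_channels=2, seed=3)
    sess, truth = ov.generate_session(cfg)
    return cfg, sess, truth, ov.build_trials(sess)


def manual_session(
    spike_times_by_unit,
    stim_specs,
    laser_specs=(),
    duration=40.0,
    lfp_rate=700.0,
    speed=None,
):
    """Hand-built session for exact-arithmetic tests.

    ``stim_specs`` is a list of (onset, duration, direction); ``speed`` an
    optional (times, values) pair, default all-still.
    """
    n = int(duration * lfp_rate)
    units = [
        ov.Unit(
            unit_id=f"u{i}",
            spike_times=np.asarray(st, dtype=float),
            mean_waveform=ov.synth.waveform_template(0.5, 0.3, 30000.0),
            waveform_rate=30000.0,
            channel_index=0,
        )
        for i, st in enumerate(spike_times_by_unit)
    ]
    if speed is None:
        t = np.arange(0.05, duration, 0.1)
        v = np.zeros_like(t)
    else:
        t, v = speed
    return ov.Session(
        subject_id="manual",
        region="V1",
        opsin="ChR2",
        lfp=np.zeros((1, n)),
        lfp_rate=lfp_rate,
        channel_depths=np.array([100.0]),
        channel_shanks=np.array([0]),
        units=units,
        speed=ov.SpeedTrace(t=t, v=v),
        stimulus_events=[
            ov.StimulusEvent(onset=o, duration=d, kind="grating", direction=dd)
            for o, d, dd in stim_specs
        ],
        laser_events=[ov.LaserEvent(onset=o, duration=d) for o, d in laser_specs],
    )


@pytest.fixture
def make_session():
    return manual_session
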