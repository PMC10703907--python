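import numpy as np
import pytest

import gutflow as gf


def make_channel(channel_id, values, dt=0.05, t0=0.0):
    return gf.TimeSeriesChannel(channel_id, t0, dt, np.asarray(values, float))


def sine_channel(channel_id="longitudinal", freq=0.7, amp=0.5, duration=60.0,
                 dt=0.05, baseline=5.0, noise_sd=0.0, seed=0):
    """Baseline + amp*sin sine trace; amp is the sine coefficient (half the
    crest-to-trough swing)."""
    t = np.arange(0.0, duration, dt)
    y = baseline + amp * np.sin(2 * np.pi * freq * t)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return make_channel(channel_id, y, dt=dt)


def flat_recording(duration=10.0, pressure=1.5, diameter=3.0, longi=5.0,
                   drops=()):
    """A recording of constant channels, for plumbing tests."""
    n_v = int(duration / 0.05)
    n_p = int(duration / 0.002)
    channels = {
        "pressure": make_channel("pressure", np.full(n_p, pressure), dt=0.002),
        "longitudinal": make_channel("longitudinal", np.full(n_v, longi)),
    }
    for i in range(1, 5):
        channels[f"ew{i}"] = make_channel(f"ew{i}", np.full(n_v, diameter))
    return gf.MotilityRecording(
        channels=channels,
        geometry=gf.SegmentGeometry((10.0,) * 4, 45.0),
        drops=[gf.DropEvent(t, v) for t, v in drops],
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic recording with ground truth (seeded)."""
    return gf.simulate(gf.SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_phases(default_sim):
    rec, _ = default_sim
    return gf.segment_phases(rec)
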