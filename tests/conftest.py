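import numpy as np
import pytest

from impactkit.io import DT_S, N_SAMPLES, Recording, SensorCalibration
from impactkit.preprocess import AnatomicalSignals


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def time_s():
    return np.arange(N_SAMPLES) * DT_S


def make_signals(lin_acc=None, ang_vel=None) -> AnatomicalSignals:
    """AnatomicalSignals straight from raw triads (no filtering), with the
    derived channels computed by the standard integral/stencil chain."""
    from impactkit.io import GRAVITY
    from impactkit.preprocess import cumulative_trapezoid_integral, five_point_derivative

    lin_acc = np.zeros((3, N_SAMPLES)) if lin_acc is None else np.asarray(lin_acc, float)
    ang_vel = np.zeros((3, N_SAMPLES)) if ang_vel is None else np.asarray(ang_vel, float)
    lin_vel = cumulative_trapezoid_integral(lin_acc * GRAVITY, DT_S)
    ang_acc = five_point_derivative(ang_vel, DT_S)
    return AnatomicalSignals.from_triads(lin_acc, lin_vel, ang_vel, ang_acc)


@pytest.fixture
def zero_signals():
    return make_signals()


def make_recording(rid="r0", lin=None, ang=None, ir=250.0, ts=100,
                   event="ev0") -> Recording:
    return Recording(
        recording_id=rid, subject_event_id=event, trigger_timestamp=ts,
        lin_acc_device=np.zeros((3, N_SAMPLES)) if lin is None else lin,
        ang_vel_device=np.zeros((3, N_SAMPLES)) if ang is None else ang,
        ir_reading=ir)


@pytest.fixture
def identity_calib():
    return SensorCalibration()
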