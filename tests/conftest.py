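import numpy as np
import pytest

from covertest import GazeRecording, default_schedule


def make_recording(xL, xR, rate=250.0, validL=None, validR=None, t0=0.0):
    """Build a recording from position arrays; validity defaults to finiteness."""
    xL = np.asarray(xL, dtype=float)
    xR = np.asarray(xR, dtype=float)
    t = t0 + np.arange(xL.size) / rate
    if validL is None:
        validL = np.isfinite(xL)
    if validR is None:
        validR = np.isfinite(xR)
    return GazeRecording(
        t=t, xL=xL, xR=xR, validL=np.asarray(validL, bool),
        validR=np.asarray(validR, bool), rate=rate,
    )


def piecewise_trace(schedule, rate, fn_left, fn_right):
    """Sample per-eye position functions fn(phase, t_local) over a schedule."""
    n = int(round(schedule.duration * rate))
    t = schedule.start + np.arange(n) / rate
    xL = np.zeros(n)
    xR = np.zeros(n)
    for phase in schedule.phases:
        idx = (t >= phase.onset - 1e-9) & (t < phase.end - 1e-9)
        tl = t[idx] - phase.onset
        xL[idx] = fn_left(phase, tl)
        xR[idx] = fn_right(phase, tl)
    return make_recording(xL, xR, rate=rate, t0=schedule.start)


@pytest.fixture
def schedule():
    return default_schedule()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
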