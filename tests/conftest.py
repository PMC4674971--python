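import numpy as np
import pytest

from kinesmooth import MeasureParams, SampledSignal, healthy_reach, stroke_reach

FS = 100.0
DT = 1.0 / FS


@pytest.fixture(scope="session")
def params() -> MeasureParams:
    return MeasureParams()


@pytest.fixture(scope="session")
def minjerk_speed():
    """Canonical smooth reach: D = 0.1 m, T = 1 s at 100 Hz."""
    return healthy_reach(D=0.1, T=1.0, dt=DT)


@pytest.fixture(scope="session")
def stroke_speed():
    """Intermittent reach: three submovements with 0.5 s gaps."""
    return stroke_reach(D=0.1, T=1.0, dt=DT, gap=0.5, n_sub=3)


def make_signal(values: np.ndarray, dt: float = DT, t0: float = 0.0) -> SampledSignal:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    names = tuple(f"ch{i}" for i in range(values.shape[1]))
    return SampledSignal(t0, dt, names, values)
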