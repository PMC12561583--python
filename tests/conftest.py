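import numpy as np
import pytest

from crpcoord import AngleTrial


def make_sinusoid_trial(
    delta_ak: float = 0.0,
    delta_kp: float = 0.0,
    n: int = 200,
    amplitude: float = 30.0,
    baseline: float = 10.0,
    duration: float = 1.0,
    **meta,
) -> AngleTrial:
    """One full-cycle trial where the ankle lags the knee by delta_ak degrees
    and the knee lags the pelvis by delta_kp degrees."""
    t = np.linspace(0.0, duration, n)
    om = 2.0 * np.pi * t / duration
    angles = {
        "pelvis": amplitude * np.sin(om) + baseline,
        "knee": amplitude * np.sin(om - np.radians(delta_kp)) + baseline,
        "ankle": amplitude * np.sin(om - np.radians(delta_kp + delta_ak)) + baseline,
    }
    defaults = dict(
        subject_id="S01", group="control", stage="pre", trial_index=1,
        sample_rate=(n - 1) / duration,
    )
    defaults.update(meta)
    return AngleTrial(time=t, angles=angles, **defaults)


@pytest.fixture
def sinusoid_trial():
    return make_sinusoid_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
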