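import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chestwall as cw

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def layout():
    return cw.default_layout()


@pytest.fixture(scope="session")
def torso():
    return cw.TorsoSpec()


@pytest.fixture(scope="session")
def torso_frame(torso):
    frame, _ = cw.make_torso(torso)
    return frame


@pytest.fixture(scope="session")
def quiet_subject(torso):
    """Noise-free 60 s quiet-breathing recording with known ground truth."""
    traj, gt = cw.simulate_breathing(torso, cw.BreathSpec(seed=11))
    return traj, gt


@pytest.fixture(scope="session")
def quiet_series(quiet_subject, layout):
    traj, _ = quiet_subject
    return cw.compartment_volumes(traj, layout)


def sinusoid_series(
    duration_s=60.0,
    fs=60.0,
    f_breath=0.5,
    v_t=0.2,
    shares=(0.2, 0.1, 0.7),
    baseline=10.0,
    noise_sigma=0.0,
    seed=0,
):
    """Analytic compartment series: V0 + (v_t/2) * sin(2 pi f t) split by
    fixed shares, optionally with additive Gaussian noise."""
    t = np.arange(int(round(duration_s * fs))) / fs
    rng = np.random.default_rng(seed)
    wave = 0.5 * v_t * np.sin(2 * np.pi * f_breath * t)
    comps = []
    for s in shares:
        v = baseline * s + s * wave
        if noise_sigma > 0:
            v = v + rng.normal(0.0, noise_sigma * s, len(t))
        comps.append(v)
    v_rcp, v_rca, v_ab = comps
    return cw.CompartmentSeries(
        time=t,
        v_cw=v_rcp + v_rca + v_ab,
        v_rcp=v_rcp,
        v_rca=v_rca,
        v_ab=v_ab,
        sample_rate=fs,
    )
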