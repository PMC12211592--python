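import numpy as np
import pytest

import gaitspace as gs


@pytest.fixture(scope="session")
def metric6():
    return gs.metric_tensor(6)


@pytest.fixture(scope="session")
def metric8():
    return gs.metric_tensor(8)


@pytest.fixture(scope="session")
def models6():
    return gs.model_gaits(6)  # [ABT, MT]


def make_trial(gait="ALT", duty=0.5, noise_sd=0.0, seed=1, **kw):
    cfg = gs.SyntheticTrialConfig(
        gait=gait, duty_factor=duty, tracking_noise_sd=noise_sd, seed=seed, **kw
    )
    return gs.synth_trial(cfg)


@pytest.fixture(scope="session")
def alt_trial():
    """Noiseless eight-leg alternating-tetrapod trial."""
    return make_trial("ALT")


@pytest.fixture(scope="session")
def mt_trial():
    """Noiseless six-leg modified-tripod trial."""
    return make_trial("MT")


def circular_mean_cycles(points):
    """Per-coordinate circular mean of gait points, in [0, 1)."""
    ang = 2 * np.pi * np.asarray(points)
    return (np.arctan2(np.sin(ang).mean(0), np.cos(ang).mean(0)) / (2 * np.pi)) % 1
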