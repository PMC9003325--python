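import logging

import numpy as np
import pytest

import gaitinit as gi

# detection landmarks are logged at INFO; keep test output quiet
logging.getLogger("gaitinit").setLevel(logging.ERROR)

#: the four group presets with their published mean event times
PRESET_MEAN_EVENTS = {
    "PD": (0.45, 1.26, 1.73),
    "FOGminus": (0.44, 1.32, 1.81),
    "FOGplus": (0.46, 1.21, 1.67),
    "ELD": (0.42, 1.01, 1.44),
}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def zero_noise_spec(t_apa, t_to, t_hs, **kw):
    return gi.SyntheticTrialSpec(t_apa=t_apa, t_to=t_to, t_hs=t_hs,
                                 noise_sd_accel=0.0, noise_sd_cop=0.0,
                                 noise_sd_marker=0.0, **kw)


@pytest.fixture(scope="session")
def study7():
    """The default validation study: 25 PD-like + 8 elderly-control-like
    subjects, five trials each, both modalities, seed 7."""
    return gi.run_study(seed=7)


@pytest.fixture
def pd_trial_pair():
    """One noiseless paired trial at the PD mean event times."""
    spec = zero_noise_spec(0.45, 1.26, 1.73, trial_id="pd_mean",
                           subject_id="PD00")
    return spec, gi.synthesize_accel(spec), gi.synthesize_forceplate(spec)
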