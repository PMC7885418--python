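"""Shared fixtures: small synthetic sessions and calibrated models.

Expensive artifacts are session-scoped so the whole suite pays for each
calibration once.
"""

import numpy as np
import pytest

from emgdecode import calibration as cal
from emgdecode import envelope as envmod
from emgdecode import lda as ldamod
from emgdecode import network as nw
from emgdecode import synth

SMALL_TOPOLOGY = nw.Topology(
    n_inputs=3, n_dofs=2, first_layer_log2=3, encoder_depth=2, decoder_hidden_log2=2
)


@pytest.fixture(scope="session")
def profile():
    return synth.make_subject_profile(seed=1)


@pytest.fixture(scope="session")
def short_protocol():
    return synth.AcquisitionProtocol(
        repetitions=2, movement_duration=3.0, rest_duration=2.0
    )


@pytest.fixture(scope="session")
def session_data(profile, short_protocol):
    rng = np.random.default_rng(1)
    return synth.generate_calibration_session(profile, short_protocol, rng)


@pytest.fixture(scope="session")
def preprocessed(session_data):
    rec, stim = session_data
    env, stats = envmod.preprocess(rec)
    return env, stats, stim


@pytest.fixture(scope="session")
def calibrated_subject():
    from emgdecode import study

    return study.calibrate_subject(seed=1)


@pytest.fixture(scope="session")
def lda_calibrated(session_data):
    rec, stim = session_data
    return ldamod.calibrate_from_session(rec, stim)
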