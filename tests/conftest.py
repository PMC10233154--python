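"""Shared fixtures: small seeded synthetic sessions and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ssvep_assess.recording_io import extract_epochs
from ssvep_assess.synthetic_data import (
    DEFAULT_FREQUENCIES,
    StimulusSpec,
    SyntheticConfig,
    TrialTiming,
    generate_session,
)


@pytest.fixture(scope="session")
def stimulus() -> StimulusSpec:
    return StimulusSpec(paradigm="OOR", frequencies=DEFAULT_FREQUENCIES,
                        n_targets=5)


@pytest.fixture(scope="session")
def timing() -> TrialTiming:
    return TrialTiming()


@pytest.fixture(scope="session")
def oor_run_0db(stimulus, timing):
    """One 20-trial OOR recording at 0 dB target SNR (4 per frequency)."""
    cfg = SyntheticConfig(seed=11, target_snr_db=0.0)
    return generate_session(cfg, stimulus, timing, trials_per_frequency=4,
                            paradigms=("OOR",))["OOR"]


@pytest.fixture(scope="session")
def stim_epochs_0db(oor_run_0db):
    return extract_epochs(oor_run_0db, "stimulation")


@pytest.fixture(scope="session")
def detection_epochs_0db(oor_run_0db):
    return extract_epochs(oor_run_0db, "detection")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
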