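from datetime import datetime

import numpy as np
import pytest

from bloomphen import (CorrectionsConfig, SyntheticScenario, VerticalProfile,
                       generate_profile_series, generate_satellite_series)


def make_profile(depth, **vectors):
    """Bare profile on an arbitrary grid for unit tests."""
    return VerticalProfile(profile_id="t", timestamp=datetime(2016, 1, 1, 12),
                           lon=34.5, lat=27.0, depth=np.asarray(depth, float),
                           **{k: np.asarray(v, float) for k, v in vectors.items()})


@pytest.fixture(scope="session")
def clean_scenario():
    """Noise-free, gap-free, unquenched coupled scenario (planted truth)."""
    return SyntheticScenario(noise_cv=0.0, gap_fraction=0.0,
                             npq_depression=0.0, seed=42)


@pytest.fixture(scope="session")
def clean_world(clean_scenario):
    profiles, truth = generate_profile_series(clean_scenario)
    matchups = generate_satellite_series(clean_scenario, profiles)
    return clean_scenario, profiles, truth, matchups


@pytest.fixture(scope="session")
def clean_corrections():
    """Corrections matching the noise-free scenario: no quench channel."""
    return CorrectionsConfig(npq=False, calibration_factor=None)
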