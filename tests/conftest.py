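"""Shared fixtures: small synthetic cohorts and canonical signals."""

import numpy as np
import pytest

import rigipose as rp
from rigipose.features import FeatureExtractionConfig
from rigipose.pipeline import preprocess_cohort
from rigipose.signals import SignalChannel


@pytest.fixture(scope="session")
def small_cohort():
    """16-subject cohort, all 11 motions, default study conditions."""
    return rp.simulate_cohort(rp.SyntheticCohortConfig(n_subjects=16, seed=7))


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    clean = preprocess_cohort(small_cohort.recordings)
    return rp.extract_cohort_features(clean, FeatureExtractionConfig())


@pytest.fixture
def sine_channel():
    """Factory for pure sinusoid channels: sin(2*pi*f*t) at 20 fps."""

    def make(freq=2.0, duration=10.0, fs=20.0, amplitude=1.0, phase=0.0,
             offset=0.0, noise_sd=0.0, seed=0, name="sine"):
        t = np.arange(int(round(duration * fs))) / fs
        values = offset + amplitude * np.sin(2 * np.pi * freq * t + phase)
        if noise_sd > 0:
            values = values + np.random.default_rng(seed).normal(
                0.0, noise_sd, size=t.size
            )
        return SignalChannel(name=name, values=values, frame_rate=fs)

    return make
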