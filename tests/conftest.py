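"""Shared fixtures: tiny audio clips, a small fitted pipeline, and the
session-cached synthetic study runs (generated programmatically; no
stored audio fixtures)."""

from __future__ import annotations

import numpy as np
import pytest

from flightcall import (
    ARCHETYPES,
    AudioClip,
    SceneSpec,
    SpectrogramConfig,
    mix_scene,
    synth_call,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tone_clip():
    """1 s pure 4 kHz tone at 22050 Hz."""
    sr = 22050
    t = np.arange(sr) / sr
    return AudioClip(0.4 * np.sin(2 * np.pi * 4000.0 * t), sr)


@pytest.fixture()
def noise_clip():
    gen = np.random.default_rng(7)
    return AudioClip(0.2 * gen.standard_normal(22050), 22050)


@pytest.fixture()
def short_config():
    return SpectrogramConfig()


@pytest.fixture(scope="session")
def call_scene():
    """A 1-s wind scene containing a centered down-sweep call at 10 dB."""
    call = synth_call(ARCHETYPES["dsw"], seed=5)
    return mix_scene(call, SceneSpec(background="wind", snr_db=10.0, seed=6))


@pytest.fixture(scope="session")
def nclass_run():
    from flightcall.experiments import run_nclass_experiment

    return run_nclass_experiment(seed=0)


@pytest.fixture(scope="session")
def monitoring_run():
    from flightcall.experiments import run_monitoring_experiment

    return run_monitoring_experiment(seed=0)
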