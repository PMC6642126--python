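import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import abrgap as ag

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

FS = 100_000.0
DUMMY_CONDITION = ag.StimulusCondition(nb1_ms=10.0, gap_ms=5.0)


def make_epoch(samples, alignment="NB1", fs=FS, condition=DUMMY_CONDITION):
    return ag.OnsetEpoch(
        samples_uv=np.asarray(samples, float),
        sampling_rate_hz=fs,
        alignment=alignment,
        condition=condition,
        subject_id="s00",
    )


def tone_epoch(freq_hz, amplitude=1.0, fs=FS, **kwargs):
    t = np.arange(int(round(0.008 * fs))) / fs
    return make_epoch(amplitude * np.sin(2 * np.pi * freq_hz * t), fs=fs, **kwargs)


@pytest.fixture
def epoch_factory():
    return make_epoch


@pytest.fixture
def tone_factory():
    return tone_epoch


@pytest.fixture
def noise_free_config():
    return ag.GeneratorConfig(noise_sd_uv=0.0)


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline on the standard study conditions (8 subjects x 16
    conditions, master seed 1); shared across tests because it is the
    expensive common case."""
    return ag.run_pipeline(ag.PipelineConfig(seed=1))
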