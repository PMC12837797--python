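import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import lumbarload as ll

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_config() -> ll.SyntheticConfig:
    """Noise-free study conditions at a reduced sampling resolution."""
    return ll.SyntheticConfig(
        seed=7,
        n_subjects=3,
        emg_sampling_rate=250.0,
        kinematic_sampling_rate=50.0,
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noisy_config(clean_config) -> ll.SyntheticConfig:
    return dataclasses.replace(clean_config, noise_sd=0.02, seed=8)


@pytest.fixture(scope="session")
def clean_dataset(clean_config) -> ll.SubjectDataset:
    return ll.generate_subject_dataset(clean_config, 0)


@pytest.fixture(scope="session")
def clean_baselines(clean_dataset):
    return {ch: ll.compute_rest_baseline(tr) for ch, tr in clean_dataset.rest.items()}


@pytest.fixture(scope="session")
def clean_calibration(clean_dataset, clean_baselines) -> ll.SubjectCalibration:
    return ll.calibrate_subject(
        clean_dataset.subject, clean_dataset.vcts, rest_baselines=clean_baselines
    )
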