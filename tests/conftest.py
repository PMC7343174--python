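import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

logging.getLogger("graspid").setLevel(logging.ERROR)

import graspid as g  # noqa: E402


@pytest.fixture(scope="session")
def noise_free_config():
    return g.SyntheticConfig(
        n_subjects=2, n_objects=1, n_trials_per_object=1,
        trial_noise_scale=0.0, mains_noise_amplitude=0.0,
        sensor_noise_std=0.0, marker_noise_std_mm=0.0, seed=3,
    )


@pytest.fixture(scope="session")
def noise_free_trial(noise_free_config):
    profile = g.generate_subject_profile(noise_free_config, 0)
    trial = g.generate_trial(profile, "tennis_ball", 0, noise_free_config, object_index=0)
    return profile, trial


@pytest.fixture(scope="session")
def small_study():
    """8 subjects x 2 objects x 5 trials at default noise, fully extracted."""
    cfg = g.SyntheticConfig(n_subjects=8, n_objects=2, n_trials_per_object=5, seed=42)
    dataset = g.generate_dataset(cfg)
    dm = g.build_dataset_matrix(dataset, seed=42)
    return cfg, dataset, dm


@pytest.fixture(scope="session")
def planted_coded():
    """Coded planted-feature dataset: 3 informative rows of 8 binary-code
    subject identity for 8 subjects."""
    informative = (0, 2, 5)
    ds = g.generate_feature_dataset(
        n_subjects=8, n_trials_per_subject=7, informative=informative,
        n_features=8, n_samples=150, effect_scale=2.0, noise_scale=0.4,
        structure="coded", seed=0,
    )
    return informative, ds


@pytest.fixture(scope="session")
def fast_settings():
    return g.PipelineSettings(perplexity=10, tsne_max_iter=300)
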