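import numpy as np
import pytest

from facejudge.model_fitting import FitConfig
from facejudge.synthetic_data import FeatureSpaceSpec, SyntheticWorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact two-space world reused by fitting/evaluation tests."""
    cfg = SyntheticWorldConfig(
        n_latent=2,
        n_train_faces=120,
        n_test_faces=60,
        n_attributes=4,
        rating_noise_sd=1.0,
        n_raters=30,
        feature_space_specs=[
            FeatureSpaceSpec("strong", 24, 0.9, 0.05, 0.2, 0.1),
            FeatureSpaceSpec("weak", 16, 0.5, 0.3, 0.6, 0.9),
        ],
        seed=42,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def fast_fit_config():
    return FitConfig(method="ridge", n_cv_iterations=30, seed=7)


@pytest.fixture(scope="session")
def small_models(small_world, fast_fit_config):
    from facejudge.model_fitting import fit_all_attributes

    return fit_all_attributes(
        small_world.train_features["strong"], small_world.train_ratings, fast_fit_config
    )
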