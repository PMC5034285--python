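import pytest

from larvavr import KinematicsPipeline, default_true_models, make_library


@pytest.fixture(scope="session")
def true_models():
    return default_true_models()


@pytest.fixture(scope="session")
def clean_library(true_models):
    """Small noiseless library generated by the ground-truth ARX triple."""
    return make_library(30, models=true_models, noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def pipeline(true_models):
    return KinematicsPipeline(true_models)
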