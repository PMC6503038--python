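import pytest

from brainage import CVSettings, GeneratorConfig, generate_training_cohort, train_brain_age
from brainage.workflows import train_study_models

#: boosting overrides for quick unit-test models: a large learning rate and
#: few rounds are fine when we only probe structural behaviour
FAST_PARAMS = {"eta": 0.3}


def fast_cv(outer: int = 0) -> CVSettings:
    return CVSettings(outer_folds=outer, inner_folds=3, max_rounds=300, early_stopping_rounds=20)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down generator for structural tests (3 features per region)."""
    return GeneratorConfig(n_train_hc=160, n_test_hc=60, n_ms=60, features_per_region=3)


@pytest.fixture(scope="session")
def small_training(small_config):
    return generate_training_cohort(small_config, seed=5)


@pytest.fixture(scope="session")
def small_model(small_training):
    return train_brain_age(small_training, "global", cv=fast_cv(), seed=1, params=FAST_PARAMS)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def study_models(default_config):
    """Full-scale global + subcortical/cerebellar brain-age models trained on
    the default synthetic healthy cohort; shared by the recovery tests."""
    return train_study_models(default_config, seed=1234)
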