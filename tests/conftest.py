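import warnings

import numpy as np
import pytest

from evtdelay import default_fixture
from evtdelay.config import ModelConfig


def make_fixture() -> ModelConfig:
    """Fresh base-case config; the published hazard-ratio ranges trigger a
    known warn-only validation notice, silenced here."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return default_fixture()


@pytest.fixture(scope="session")
def base_config() -> ModelConfig:
    return make_fixture()


@pytest.fixture()
def config() -> ModelConfig:
    """A mutable per-test copy of the base case."""
    return make_fixture().model_copy(deep=True)


def short_horizon(cfg: ModelConfig, n_years: int) -> ModelConfig:
    """Copy of cfg truncated to an n-year horizon (for small exact checks)."""
    out = cfg.model_copy(deep=True)
    out.horizon_age_cap = out.start_age + n_years
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
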