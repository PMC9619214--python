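import numpy as np
import pytest

from survecon.config import CEModel, load_config
from survecon.simulate import make_fixture_study

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def china_itt_dir(tmp_path_factory):
    """A written China ITT fixture study (curves, risk tables, config)."""
    d = tmp_path_factory.mktemp("china_itt")
    study = make_fixture_study("china", "itt", seed=FIXTURE_SEED)
    study.write(d)
    return d


@pytest.fixture(scope="session")
def china_itt_config(china_itt_dir):
    return load_config(china_itt_dir / "config.yaml")


@pytest.fixture(scope="session")
def china_itt_model(china_itt_config):
    """Curves resolved once per session; evaluation itself is cheap."""
    return CEModel(china_itt_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
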