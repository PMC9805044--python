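import numpy as np
import pytest

from sdmuq.config import ExperimentConfig
from sdmuq.forcing import EsmStyle, default_styles, generate_forcing
from sdmuq.grids import GridSpec
from sdmuq.operating_model import default_archetypes, draw_truth


@pytest.fixture(scope="session")
def default_grid() -> GridSpec:
    return GridSpec()


@pytest.fixture(scope="session")
def quiet_style() -> EsmStyle:
    """A style with no noise, no cycle, no trend: every year equals the base."""
    return EsmStyle(esm_id="quiet", trend_per_decade={}, decadal_amplitude={},
                    noise_sd={}, nearshore_amplification=1.0)


@pytest.fixture(scope="session")
def default_env(default_grid):
    """One default pseudo-ESM forcing realisation on the full default grid."""
    return generate_forcing(default_grid, default_styles()[0], seed=11)


@pytest.fixture(scope="session")
def hms_truth(default_env):
    return draw_truth(default_env, default_archetypes()["HMS"], seed=11)


@pytest.fixture(scope="session")
def default_result(tmp_path_factory):
    """The full default synthetic experiment (shared across acceptance tests).

    0.5 degree grid, 3 pseudo-ESMs, the 12-member retained roster plus the
    temperature-only variants, fixed master seed.  Takes several minutes;
    computed once per session.
    """
    from sdmuq.pipeline import run_experiment

    cfg = ExperimentConfig(master_seed=0)
    out = tmp_path_factory.mktemp("default_experiment")
    return run_experiment(cfg, out)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
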