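import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lncnet import AnalysisConfig, ExpressionMatrix
from lncnet.simulate import SimulationConfig, assemble_fixture

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 probes x 4 samples, two groups of two."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 5.5, 4.0, 4.5],
         [2.0, 2.0, 2.0, 2.0]],
        index=["P1", "P2", "P3"],
        columns=["c1", "c2", "n1", "n2"])
    groups = pd.Series(["case", "case", "control", "control"],
                       index=["c1", "c2", "n1", "n2"])
    return ExpressionMatrix(values, groups)


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A compact study: 400 mRNA / 120 lncRNA probes, all structures planted."""
    return SimulationConfig(n_mrna=400, n_lncrna=120, n_background_terms=10,
                            n_background_tf=10, seed=11)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_sim_config):
    out = tmp_path_factory.mktemp("bundle")
    paths = assemble_fixture(small_sim_config, out)
    return paths


@pytest.fixture
def default_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
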