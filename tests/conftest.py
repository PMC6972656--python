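import warnings

import numpy as np
import pytest

from vtamosaic import pipeline, synthetic
from vtamosaic.synthetic import SimulationConfig, default_truth_table


@pytest.fixture(scope="session")
def truth():
    return default_truth_table()


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, truth, sim_config):
    """One materialized synthetic study shared by the integration tests."""
    d = tmp_path_factory.mktemp("study")
    synthetic.write_inputs(d, truth, sim_config,
                           cell_candidates={"Cbln4": 0.38, "Gpr101": 0.46})
    return d


@pytest.fixture(scope="session")
def study_inputs(study_dir):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.load_inputs(study_dir)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
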