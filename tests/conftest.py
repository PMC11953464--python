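import numpy as np
import pytest

from prpdecode.behavior import StageModel, simulate_behavior
from prpdecode.bold import NoiseConfig, synthesize_bold
from prpdecode.design import DesignSpec, make_design
from prpdecode.regions import RegionModel


@pytest.fixture(scope="session")
def tiny_spec():
    """Two short runs of the two single-task conditions."""
    return DesignSpec(n_runs=2, trials_per_run=16, run_volumes=600,
                      conditions=("AO", "VM"), seed=0)


@pytest.fixture(scope="session")
def tiny_session(tiny_spec):
    """A small simulated subject: trials, one central region, BOLD runs."""
    rng = np.random.default_rng(11)
    trials = simulate_behavior(make_design(tiny_spec, rng), StageModel(), rng)
    md = RegionModel("MD", "central", None, n_voxels=40)
    runs = synthesize_bold(trials, [md], tiny_spec, NoiseConfig(), rng)
    return {"spec": tiny_spec, "trials": trials, "runs": runs}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
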