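import numpy as np
import pytest
from hypothesis import settings

import sdpfit as s

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dppc():
    return s.builtin_lipid("DPPC")


@pytest.fixture(scope="session")
def solvent():
    return s.SolventSpec()


@pytest.fixture(scope="session")
def dppc_template(dppc):
    return s.template_structure(dppc)


@pytest.fixture(scope="session")
def dppc_profiles(dppc_template, dppc, solvent):
    return s.build_profiles(dppc_template, dppc, solvent)


@pytest.fixture(scope="session")
def small_experiment(dppc):
    """A reduced-size noisy joint SAXS + SANS(100% D2O) campaign."""
    design = s.ExperimentDesign(q_xray=np.linspace(0.01, 0.6, 200),
                                q_neutron=np.linspace(0.01, 0.3, 80))
    truth = s.make_truth(dppc, seed=101)
    experiment = s.simulate_experiment(truth, dppc, design, seed=102,
                                       n_sans=1)
    return truth, experiment
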