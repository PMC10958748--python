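import numpy as np
import pytest

from gapddm.core import ModelParams
from gapddm.kinematics import Condition
from gapddm.synth import (
    DEFAULT_GROUP_MEAN_PARAMS,
    PopulationSpec,
    apply_exclusions,
    generate_dataset,
)

#: the parameter set generating all recovery-style fixtures
TRUTH = DEFAULT_GROUP_MEAN_PARAMS


@pytest.fixture(scope="session")
def truth_params() -> ModelParams:
    return TRUTH


@pytest.fixture(scope="session")
def homogeneous_spec() -> PopulationSpec:
    """16 identical participants at the group-mean parameters."""
    sd0 = {k: 0.0 for k in PopulationSpec().param_sd}
    return PopulationSpec(seed=7, param_sd=sd0)


@pytest.fixture(scope="session")
def homogeneous_dataset(homogeneous_spec):
    """16 x 120 trials generated from the group-mean parameters, filtered."""
    df = generate_dataset(homogeneous_spec)
    retained, _ = apply_exclusions(df)
    return retained


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 4-participant heterogeneous dataset for plumbing tests."""
    spec = PopulationSpec(n_participants=4, seed=21)
    df = generate_dataset(spec, n_routes=2)
    retained, _ = apply_exclusions(df)
    return retained


@pytest.fixture(scope="session")
def condition_grid():
    from gapddm.kinematics import make_condition_grid

    return make_condition_grid([4, 5, 6], [90, 120, 150])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
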