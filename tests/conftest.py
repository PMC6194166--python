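import numpy as np
import pytest

from embryoscope.observer_models import ObserverState, PrototypeLearner
from embryoscope.shape_space import (
    build_shape_space,
    generate_base_population,
    tune_category_pair,
)


@pytest.fixture(scope="session")
def small_population():
    """Tiny mesh population: big enough for >=3 PCs, fast to decompose."""
    return generate_base_population(n_embryos=25, n_vertices=60, seed=42)


@pytest.fixture(scope="session")
def space(small_population):
    return build_shape_space(small_population)


@pytest.fixture(scope="session")
def pair(space):
    """Category pair at the default difficulty (ideal d' 2.5, identity cov)."""
    return tune_category_pair(space, 2.5, np.eye(2), seed=5)


@pytest.fixture(scope="session")
def criterion_pair(space):
    """Category pair at exactly the criterion d' 1.68."""
    return tune_category_pair(space, 1.68, np.eye(2), seed=5)


@pytest.fixture()
def trained_server(pair, space):
    """A server trained to criterion on the default pair."""
    from embryoscope.experiment_engine import CriterionRule, run_phase

    server = PrototypeLearner(ObserverState.untrained(), subject_id="S1")
    log = run_phase(pair, space, server, "training", CriterionRule(), seed=3)
    assert log.converged
    return server
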