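import numpy as np
import pytest

import microrefine as mr


@pytest.fixture(scope="session")
def cubic_cell():
    return mr.UnitCell(10.0, 10.0, 10.0, 90.0, 90.0, 90.0)


@pytest.fixture(scope="session")
def triclinic_cell():
    return mr.UnitCell(5.1, 7.2, 9.3, 91.0, 95.0, 102.0)


@pytest.fixture(scope="session")
def pyridine():
    return mr.make_fixture("pyridine_pair")


@pytest.fixture(scope="session")
def random_model():
    """Seeded random structure with a torus shape and mixed iso/aniso ADPs."""
    return mr.make_fixture("random_structure", seed=7, with_shape=True).model


@pytest.fixture(scope="session")
def recovery_problem():
    """Ground truth + exact data + perturbed start with a fixed origin."""
    fx = mr.make_fixture("random_structure", seed=1)
    truth = fx.model
    data = mr.simulate_observations(truth, d_min=0.9, noise_frac=0.0, seed=1)
    pert = truth.copy()
    rng = np.random.default_rng(11)
    for atom in pert.atoms[1:]:
        atom.frac = atom.frac + rng.uniform(-0.02, 0.02, 3)
    constraints = [mr.Fix(truth.atoms[0].label, ("x", "y", "z"))]
    return truth, data, pert, constraints
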