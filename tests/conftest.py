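import numpy as np
import pytest

from pfascat.config import RunConfig
from pfascat.fixtures import FixtureSpec, generate_landscape
from pfascat.pipeline import run_full_categorization

PFOA = "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"
PFOS = "OS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"
PERFLUOROSEBACAMIDINE = ("NC(=N)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)"
                         "C(F)(F)C(F)(F)C(=N)N")


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix with zero diagonal and entries in [0, 1]."""
    d = rng.random((n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def landscape(fixture_spec):
    """Synthetic landscape registry plus its ground-truth table."""
    return generate_landscape(fixture_spec)


@pytest.fixture(scope="session")
def fixture_config():
    # hybrid-rule membership threshold scaled to the fixture size so the
    # second-class branch is exercised on a ~80-substance landscape
    return RunConfig(hybrid_membership_threshold=10)


@pytest.fixture(scope="session")
def categorization(landscape, fixture_config):
    registry, _ = landscape
    return run_full_categorization(registry, fixture_config)
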