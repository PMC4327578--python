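import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssabatch import crs_from_model, decay_dimerization, dense_from_model, gene_battery

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def decay_model():
    return decay_dimerization()


@pytest.fixture(scope="session")
def decay_dense(decay_model):
    return dense_from_model(decay_model)


@pytest.fixture(scope="session")
def decay_crs(decay_model):
    return crs_from_model(decay_model)


@pytest.fixture(scope="session")
def battery_model():
    return gene_battery(4)


def random_valid_model(rng: np.random.Generator, m_max: int = 6, n_max: int = 8):
    """Random well-formed mass-action model (orders 0-2, integer counts)."""
    from ssabatch import ModelSpec, ReactionSpec

    m = int(rng.integers(1, m_max + 1))
    n = int(rng.integers(1, n_max + 1))
    reactions = []
    for j in range(n):
        order = int(rng.integers(0, 3))
        if order == 0:
            reactants = ()
        elif order == 1:
            reactants = ((int(rng.integers(0, m)), 1),)
        elif rng.random() < 0.5 or m < 2:
            reactants = ((int(rng.integers(0, m)), 2),)
        else:
            s1, s2 = rng.choice(m, size=2, replace=False)
            reactants = ((int(s1), 1), (int(s2), 1))
        n_prod = int(rng.integers(0, 3))
        prods = rng.choice(m, size=min(n_prod, m), replace=False)
        products = tuple((int(s), int(rng.integers(1, 3))) for s in prods)
        # short-decimal rate constants survive SBML's 15-digit double printing
        reactions.append(
            ReactionSpec(f"r{j}", round(float(rng.uniform(0.01, 2.0)), 6), reactants, products)
        )
    counts = tuple(int(x) for x in rng.integers(0, 50, size=m))
    return ModelSpec(tuple(f"X{i}" for i in range(m)), counts, tuple(reactions))
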