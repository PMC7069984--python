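import numpy as np
import pandas as pd
import pytest

from tinndep import (
    GeneratorConfig, assemble_features, default_schema, generate_cohort,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_patients=400, seed=123))


@pytest.fixture(scope="session")
def small_features(small_cohort, schema):
    return assemble_features(small_cohort, schema)


@pytest.fixture()
def toy_xy():
    """A tiny separable two-feature problem."""
    rng = np.random.default_rng(5)
    n = 80
    x1 = np.concatenate([rng.normal(-2, 0.5, n // 2),
                         rng.normal(2, 0.5, n // 2)])
    x2 = rng.standard_normal(n)
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame({"x1": x1, "x2": x2})
    return X, y
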