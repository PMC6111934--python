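import numpy as np
import pytest

import zspose as z


@pytest.fixture(scope="session")
def schema():
    return z.default_schema()


@pytest.fixture(scope="session")
def defs():
    return z.default_definitions()


@pytest.fixture(scope="session")
def importance():
    return z.default_importance()


@pytest.fixture(scope="session")
def def_mat(schema, defs):
    """Expanded definition matrix (22, 33) plus class order."""
    return z.expand_definition_table(defs, schema)


@pytest.fixture(scope="session")
def def_protos(def_mat):
    mat, classes = def_mat
    return [z.ClassPrototype(c, v, "definition") for c, v in zip(classes, mat)]


def random_valid_vectors(schema, n, rng):
    """Uniformly random valid attribute vectors (simplex slices Dirichlet-flat)."""
    X = np.zeros((n, schema.D))
    for j in schema:
        sl = schema.slices[j.name]
        if j.kind == "classification":
            X[:, sl] = rng.dirichlet(np.ones(j.dim), size=n)
        else:
            X[:, sl.start] = rng.random(n)
    return X
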