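import numpy as np
import pytest

from orphanfit.model_core import MetabolicModel, Reaction, parse_gpr
from orphanfit.profiles import ProfileMatrix
from orphanfit.synthetic import FixtureSpec, make_toy_model, simulate_fitness


@pytest.fixture
def tiny_model():
    """Three reactions in a chain, one orphan in the middle."""
    return MetabolicModel(
        reactions=[
            Reaction(id="R1", stoich={"A": -1, "B": 1}, gpr=parse_gpr("g1")),
            Reaction(id="R2", stoich={"B": -1, "C": 1}, gpr=None),
            Reaction(id="R3", stoich={"C": -1, "D": 1}, gpr=parse_gpr("g2 and g3")),
        ]
    )


@pytest.fixture(scope="session")
def default_fixture():
    """Session-shared synthetic fixture at the default study conditions."""
    spec = FixtureSpec(seed=7)
    model, truth = make_toy_model(spec)
    sim = simulate_fitness(model, truth, spec)
    return spec, model, truth, sim


@pytest.fixture(scope="session")
def noisefree_fixture():
    """Noise-free fixture used for exact-recovery checks."""
    spec = FixtureSpec(seed=11, noise_sd=0.0, orphan_fraction=0.0)
    model, truth = make_toy_model(spec)
    sim = simulate_fitness(model, truth, spec)
    return spec, model, truth, sim


def random_profile_matrix(rng, n_rows=8, n_cols=6, prefix="g"):
    values = rng.standard_normal((n_rows, n_cols))
    import pandas as pd

    df = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(n_rows)],
        columns=[f"c{j}" for j in range(n_cols)],
    )
    return ProfileMatrix(df)
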