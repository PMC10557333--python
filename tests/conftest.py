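import numpy as np
import pandas as pd
import pytest

import crashpath as cp


@pytest.fixture(scope="session")
def toy_specs():
    return (
        cp.VariableSpec("exposure", "predictor", "binary", ("no", "yes")),
        cp.VariableSpec("severity", "predictor", "ordinal", ("low", "mid", "high", "max")),
        cp.VariableSpec("color", "predictor", "nominal", ("red", "green", "blue", "gray")),
        cp.VariableSpec("outcome", "outcome", "binary", ("alive", "dead")),
    )


@pytest.fixture(scope="session")
def toy_table(toy_specs):
    df = pd.DataFrame({
        "exposure": ["no", "yes", "yes", "no", "yes", "no"],
        "severity": ["low", "mid", "high", "max", "mid", "low"],
        "color": ["red", "green", "blue", "gray", "red", "green"],
        "outcome": ["alive", "dead", "dead", "alive", "alive", "dead"],
    })
    return cp.load_table(df, toy_specs)


@pytest.fixture(scope="session")
def crash_table():
    """One registry-scale synthetic study (n=742)."""
    spec = cp.default_crash_spec(n=742, seed=20240901)
    table, truth = cp.simulate_structural(spec)
    return table, truth, spec


@pytest.fixture(scope="session")
def benchmark():
    """Sparse-signal logistic benchmark with 4 true among 28 predictors."""
    table, truth = cp.simulate_selection_benchmark(n=2000, seed=20240902)
    return table, truth


@pytest.fixture(scope="session")
def logit_toy():
    """Well-behaved logistic data, no separation, for lambda=0 oracles."""
    rng = np.random.default_rng(17)
    n, p = 300, 4
    X = rng.standard_normal((n, p))
    beta = np.array([0.9, -0.5, 0.0, 0.6])
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-(0.2 + X @ beta)))).astype(float)
    return X, y
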