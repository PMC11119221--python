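import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mixedexplore as mx

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def eq_full():
    """Full-model spec with two free predictors (both slope candidates)
    and one forced covariate — the worked two-predictor example."""
    return mx.parse_formula(
        "Y ~ X1 + X2 + X3", group="G", slopes=["X1", "X2"], forced=["X3"]
    )


@pytest.fixture(scope="session")
def toy_lmm_data():
    """30-row, 3-group dataset with a known random-intercept structure."""
    rng = np.random.default_rng(2024)
    groups = np.repeat(["a", "b", "c"], 10)
    b = {"a": 1.2, "b": -0.7, "c": 0.1}
    x = rng.standard_normal(30)
    y = 0.5 + 0.8 * x + np.array([b[g] for g in groups]) + 0.6 * rng.standard_normal(30)
    return pd.DataFrame({"y": y, "x": x, "g": groups})


@pytest.fixture(scope="session")
def sim_small():
    """Small two-predictor simulated dataset with a true x1 random slope."""
    spec = mx.SimSpec(
        n_groups=25,
        group_sizes=40,
        beta={"(Intercept)": 1.0, "x1": 0.8, "x2": 0.3},
        psi=((1.0, 0.2), (0.2, 0.25)),
        sigma=1.0,
        slope_terms=("x1",),
        seed=42,
    )
    return spec, mx.simulate_dataset(spec)
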