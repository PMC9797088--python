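import numpy as np
import pandas as pd
import pytest

from forestnet.decisions import Condition, DecisionEnsemble, decision_from_rule, make_rule
from forestnet.model_io import make_dataset


@pytest.fixture
def toy_data():
    """Small handmade classification dataset: 2 numerics + a 3-level factor."""
    rng = np.random.default_rng(42)
    n = 60
    X = pd.DataFrame(
        {
            "V1": rng.normal(0.5, 1.0, n),
            "V2": rng.normal(0.5, 1.0, n),
            "grp": pd.Categorical(rng.choice(["a", "b", "c"], n)),
        }
    )
    y = ((X["V1"] > 0.5) & (X["grp"] == "a")).astype(float).to_numpy()
    # sprinkle noise so errors are nontrivial
    flip = rng.random(n) < 0.1
    y = np.where(flip, 1 - y, y)
    return make_dataset(X, y, "classification")


@pytest.fixture
def reg_data():
    rng = np.random.default_rng(7)
    n = 50
    X = pd.DataFrame({"x1": rng.normal(0, 1, n), "x2": rng.normal(0, 1, n)})
    y = 2.0 * X["x1"].to_numpy() + rng.normal(0, 0.3, n)
    return make_dataset(X, y, "regression")


@pytest.fixture
def toy_ensemble(toy_data):
    """Three hand-built decisions over toy_data."""
    rules = [
        make_rule([Condition("V1", lo=0.5), Condition("grp", levels=("a",))]),
        make_rule([Condition("V1", hi=0.5)]),
        make_rule([Condition("V2", lo=0.0), Condition("grp", levels=("b", "c"))]),
    ]
    decisions = [decision_from_rule(r, toy_data) for r in rules]
    return DecisionEnsemble(decisions=[d for d in decisions if d], data=toy_data)


@pytest.fixture
def fsd_small():
    from forestnet.simulate import simulate_fsd

    return simulate_fsd(400, 0.05, seed=3)
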