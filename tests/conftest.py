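import numpy as np
import pandas as pd
import pytest

import mome
from mome.synthetic_data import MODEL1_PRODUCTS, MODEL1_SYNTAX

# Published-style demonstration coefficient sets for the two worked models.
# Effect algebra operates on reported coefficient tables like these without
# needing the raw data.
TABLE1_COEF = {
    "m1": {"x1": 0.352, "w1": 0.022, "w1x1": 0.151, "x2": 0.158},
    "m2": {"m1": 0.548},
    "m3": {"x2": 0.495, "x1": 0.321},
    "y1": {"m2": 0.826, "w2": 0.429, "w2m2": 0.801, "x1": -0.031,
           "x2": -0.107, "m3": 0.106},
    "y2": {"m3": 0.550, "x2": -0.016, "x1": 0.029, "m2": -0.033},
}

MODEL2_SYNTAX = """\
m1 ~ x1 + w1Beta + w1Gamma + w1Betax1 + w1Gammax1 + c1 + c2
m2 ~ m1 + c1 + c2
y1 ~ m2 + w2 + w2m2 + x1 + c1 + c2
"""

MODEL2_PRODUCTS = {
    "w1Betax1": ("w1Beta", "x1"),
    "w1Gammax1": ("w1Gamma", "x1"),
    "w2m2": ("w2", "m2"),
}

TABLE2_COEF = {
    "m1": {"x1": 0.196, "w1Beta": -0.116, "w1Gamma": -0.178,
           "w1Betax1": 0.125, "w1Gammax1": 0.434},
    "m2": {"m1": 0.551},
    "y1": {"m2": 0.820, "w2": 0.439, "w2m2": 0.799, "x1": 0.005},
}


@pytest.fixture(scope="session")
def model1():
    return mome.parse_model(MODEL1_SYNTAX, products=MODEL1_PRODUCTS)


@pytest.fixture(scope="session")
def table1_est(model1):
    return mome.ParamEstimates.from_coefficients(model1, TABLE1_COEF)


@pytest.fixture(scope="session")
def model2():
    return mome.parse_model(MODEL2_SYNTAX, products=MODEL2_PRODUCTS)


@pytest.fixture(scope="session")
def table2_est(model2):
    return mome.ParamEstimates.from_coefficients(model2, TABLE2_COEF)


SIMPLE_MEDIATION_SYNTAX = "m ~ x\ny ~ m + x"


@pytest.fixture(scope="session")
def mediation_model():
    return mome.parse_model(SIMPLE_MEDIATION_SYNTAX)


@pytest.fixture(scope="session")
def mediation_data():
    from mome.synthetic_data import generate, simple_mediation_spec

    spec = simple_mediation_spec(n=200, a=0.3, b=0.3, cp=0.1, seed=99)
    data, truth = generate(spec)
    return data, truth


def random_dag_model(rng, n_nodes=6, p_edge=0.4):
    """A random DAG as model syntax over ordered nodes v0 < v1 < ... ."""
    nodes = [f"v{i}" for i in range(n_nodes)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    preds = {}
    for u, v in edges:
        preds.setdefault(v, []).append(u)
    lines = [f"{v} ~ " + " + ".join(us) for v, us in preds.items()]
    return nodes, edges, "\n".join(lines)
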