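import warnings

import numpy as np
import pandas as pd
import pytest

from sepira import (
    BuildParams,
    ExpressionMatrix,
    RegulatoryNetwork,
    SimConfig,
    build_network,
    simulate_dnam,
    simulate_expression,
)


@pytest.fixture(scope="session")
def sim_default():
    """Reference simulated compendium (seed 1) with its planted ground truth."""
    cfg = SimConfig(seed=1)
    expr, truth = simulate_expression(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def built_network(sim_default):
    """Network built from the reference compendium, plus the stage report."""
    _, expr, truth = sim_default
    tf_ids = [g for g in expr.gene_ids if g.startswith("TF_")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net, report = build_network(expr, tf_ids, BuildParams(target_tissue="lung"))
    return net, report


@pytest.fixture(scope="session")
def sim_dnam(sim_default):
    cfg, _, truth = sim_default
    return simulate_dnam(cfg, truth)


@pytest.fixture
def toy_expr():
    """Tiny deterministic expression matrix: 4 genes x 6 samples, 3 tissues."""
    values = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            [1.0, 1.5, 0.5, 2.0, 1.0, 1.2],
        ],
        index=["gA", "gB", "gC", "gD"],
        columns=[f"s{i}" for i in range(6)],
    )
    tissues = pd.Series(
        ["liver", "liver", "brain", "brain", "skin", "skin"],
        index=values.columns,
    )
    return ExpressionMatrix(values, tissues)


@pytest.fixture
def toy_network():
    return RegulatoryNetwork(
        {
            "TF1": {"g1": 1, "g2": 1, "g3": -1},
            "TF2": {"g2": -1, "g4": 1},
        }
    )
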