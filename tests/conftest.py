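import numpy as np
import pandas as pd
import pytest

from framingnet.network import (
    CategoricalDataset,
    CPTSet,
    NetworkStructure,
    VariableSpec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def figure1():
    from framingnet.fixtures import figure1_cpts, figure1_structure

    return figure1_structure(), figure1_cpts()


@pytest.fixture(scope="session")
def figure1_population(figure1):
    """Profiled 6561-individual population (shared; expensive to rebuild)."""
    from framingnet.profiler import profile_population

    structure, cpts = figure1
    return profile_population(structure, cpts)


@pytest.fixture
def chain_ab():
    """Two-node chain A -> B with hand-set tables."""
    variables = [
        VariableSpec("A", "T1", ("a0", "a1")),
        VariableSpec("B", "OUTCOME", ("b0", "b1")),
    ]
    structure = NetworkStructure(variables, [("A", "B")])
    cpts = CPTSet(
        structure,
        {"A": np.array([[0.4, 0.6]]), "B": np.array([[0.5, 0.5], [0.1, 0.9]])},
    )
    return structure, cpts


@pytest.fixture
def six_node():
    """Six-node network mixing slices, with a hidden mediator path."""
    variables = [
        VariableSpec("u", "T1", ("low", "medium", "high")),
        VariableSpec("v", "T1", ("low", "high")),
        VariableSpec("msg", "MESSAGE", ("gain", "nonloss", "nongain", "loss")),
        VariableSpec("s", "T2", ("low", "high")),
        VariableSpec("t", "T2", ("low", "high")),
        VariableSpec("z", "OUTCOME", ("low-negative", "neutral", "low-positive")),
    ]
    arcs = [
        ("u", "z"),
        ("v", "s"),
        ("msg", "s"),
        ("msg", "z"),
        ("s", "z"),
        ("u", "t"),
    ]
    structure = NetworkStructure(variables, arcs)
    rng = np.random.default_rng(7)
    from framingnet.fixtures import random_cpts

    return structure, random_cpts(structure, rng, concentration=3.0)


@pytest.fixture
def recovery_net():
    """Chain A -> B -> C with every parent configuration well supported
    (all probabilities bounded away from 0), for parameter-recovery checks."""
    variables = [
        VariableSpec("A", "T1", ("low", "medium", "high")),
        VariableSpec("B", "T1", ("low", "medium", "high")),
        VariableSpec("C", "OUTCOME", ("low", "medium", "high")),
    ]
    structure = NetworkStructure(variables, [("A", "B"), ("B", "C")])
    cpts = CPTSet(
        structure,
        {
            "A": np.array([[0.3, 0.45, 0.25]]),
            "B": np.array([[0.6, 0.25, 0.15], [0.2, 0.55, 0.25], [0.15, 0.3, 0.55]]),
            "C": np.array([[0.5, 0.3, 0.2], [0.25, 0.5, 0.25], [0.2, 0.2, 0.6]]),
        },
    )
    return structure, cpts


def make_dataset(structure, cpts, n, seed):
    from framingnet.cohort import sample_from_network

    frame = sample_from_network(structure, cpts, n, np.random.default_rng(seed))
    return CategoricalDataset(structure, frame)


@pytest.fixture
def toy_roster():
    """Small eligibility table: 2 dieters, 3 low-meat, 1 incomplete, disjoint."""
    return pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(10)],
            "special_diet_flag": [True, True] + [False] * 8,
            "past_behavior": [5, 5, 1, 2, 0, 5, 6, 7, 8, 9],
            "complete_flag": [True] * 5 + [False] + [True] * 4,
        }
    )
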