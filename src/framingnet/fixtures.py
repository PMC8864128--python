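"""Reference network structures and ground-truth parameterizations.

``figure1_structure`` is the published three-slice network selected by the
automated elicitation on the real cohort: eight ternary Time-1
antecedents, the randomized four-level message node, systematic processing
as the single Time-2 mediator, and the five-level *Delta intention*
outcome.  Four antecedents act on the outcome directly (baseline
intention, prevention focus, perceived severity, diffused responsibility)
and four through the mediator (promotion focus, food involvement,
perceived behavioral control, desensitization).

``figure1_cpts`` attaches a synthetic ground-truth parameterization to
that structure (the study's fitted tables live with the deposited data and
are not shipped): conditional distributions follow a discretized-Gaussian
response around an additive score of parent levels, with
framing x moderator interactions engineered so that the loss framing is
most effective for the (high intention, high prevention focus, high
perceived severity) profiles -- the qualitative pattern reported for
strong meat eaters.  Effect strength is tunable.
"""

from __future__ import annotations

import json
from itertools import product
from typing import Mapping

import numpy as np

from .network import (
    FRAMINGS,
    OUTCOME_SCALE,
    TERNARY_SCALE,
    CPTSet,
    NetworkStructure,
    VariableSpec,
)

__all__ = [
    "DIRECT_MODERATORS",
    "MEDIATED_ANTECEDENTS",
    "figure1_structure",
    "figure1_cpts",
    "random_structure",
    "random_cpts",
    "load_structure",
]

DIRECT_MODERATORS: tuple[str, ...] = (
    "baseline_intention",
    "prevention_focus",
    "perceived_severity",
    "diffused_responsibility",
)
MEDIATED_ANTECEDENTS: tuple[str, ...] = (
    "promotion_focus",
    "food_involvement",
    "perceived_behavioral_control",
    "desensitization",
)

MESSAGE_NODE = "condition"
MEDIATOR_NODE = "systematic_processing"
OUTCOME_NODE = "delta_intention"


def figure1_structure() -> NetworkStructure:
    """The published time-sliced network (8 T1 nodes, 11 nodes, 11 arcs)."""
    variables = [
        VariableSpec(name, "T1", TERNARY_SCALE)
        for name in DIRECT_MODERATORS + MEDIATED_ANTECEDENTS
    ]
    variables.append(VariableSpec(MESSAGE_NODE, "MESSAGE", FRAMINGS))
    variables.append(VariableSpec(MEDIATOR_NODE, "T2", TERNARY_SCALE))
    variables.append(VariableSpec(OUTCOME_NODE, "OUTCOME", OUTCOME_SCALE))
    arcs = [(MESSAGE_NODE, OUTCOME_NODE), (MESSAGE_NODE, MEDIATOR_NODE), (MEDIATOR_NODE, OUTCOME_NODE)]
    arcs += [(v, OUTCOME_NODE) for v in DIRECT_MODERATORS]
    arcs += [(v, MEDIATOR_NODE) for v in MEDIATED_ANTECEDENTS]
    return NetworkStructure(variables, arcs)


def _gaussian_rows(scores: np.ndarray, centers: np.ndarray, tau: float) -> np.ndarray:
    """Row-stochastic table: discretized Gaussian response around a score."""
    w = np.exp(-((centers[None, :] - scores[:, None]) ** 2) / (2 * tau**2))
    return w / w.sum(axis=1, keepdims=True)


def figure1_cpts(effect_scale: float = 1.0, tau: float = 1.2) -> CPTSet:
    """Synthetic ground-truth CPTs for the published structure.

    ``effect_scale`` multiplies every structural coefficient (1.0 gives the
    strong contrasts used for recovery experiments); ``tau`` is the spread
    of the discretized-Gaussian response (larger = noisier outcome).
    """
    structure = figure1_structure()
    lvl = np.array([-1.0, 0.0, 1.0])  # centered ternary levels

    # framing response surfaces: main shift plus slopes on the centered
    # (baseline intention, prevention focus, perceived severity) moderators.
    # Chosen so each framing dominates a distinct receiver region, with loss
    # strongest for the (high, high, high) profiles
    z_framing = {
        "gain": (0.25, (0.0, -0.3, 0.5)),
        "nonloss": (0.15, (-0.4, 0.3, -0.3)),
        "nongain": (0.10, (-0.2, -0.5, 0.6)),
        "loss": (-0.20, (0.7, 0.7, 0.7)),
    }
    s_main = {"gain": -0.9, "nonloss": 0.9, "nongain": -0.4, "loss": 0.4}

    tables: dict[str, np.ndarray] = {}
    for name in DIRECT_MODERATORS + MEDIATED_ANTECEDENTS:
        tables[name] = np.array([[1 / 3, 1 / 3, 1 / 3]])
    tables[MESSAGE_NODE] = np.array([[134 / 545, 134 / 545, 136 / 545, 141 / 545]])

    # mediator | message, promotion focus, food involvement, pbc, desensitization
    rows = []
    for m in FRAMINGS:
        for combo in product(range(3), repeat=4):
            x = lvl[list(combo)]
            score = effect_scale * (0.9 * x.sum() + s_main[m])
            rows.append(score)
    tables[MEDIATOR_NODE] = _gaussian_rows(np.array(rows), np.array([-2.0, 0.0, 2.0]), 1.0)

    # outcome | message, baseline intention, prevention focus, perceived
    # severity, diffused responsibility, mediator  (parent order matches the
    # arc declaration order of figure1_structure)
    parent_names = figure1_structure().parents(OUTCOME_NODE)
    rows = []
    for combo in product(*[range(len(structure.categories(p))) for p in parent_names]):
        vals = dict(zip(parent_names, combo))
        m = FRAMINGS[vals[MESSAGE_NODE]]
        x_bi = lvl[vals["baseline_intention"]]
        x_pf = lvl[vals["prevention_focus"]]
        x_ps = lvl[vals["perceived_severity"]]
        x_dr = lvl[vals["diffused_responsibility"]]
        x_sp = lvl[vals[MEDIATOR_NODE]]
        main, (c_bi, c_pf, c_ps) = z_framing[m]
        score = effect_scale * (
            1.2 * x_bi
            + 1.0 * x_pf
            + 1.0 * x_ps
            + 0.9 * x_dr
            + 1.1 * x_sp
            + main
            + c_bi * x_bi
            + c_pf * x_pf
            + c_ps * x_ps
        )
        rows.append(score)
    tables[OUTCOME_NODE] = _gaussian_rows(
        np.array(rows), np.array([-4.0, -2.0, 0.0, 2.0, 4.0]), tau
    )
    return CPTSet(structure, tables)


# ---------------------------------------------------------------------------
# random networks (oracle cross-checks)


def random_structure(
    rng: np.random.Generator,
    n_nodes: int = 6,
    edge_prob: float = 0.4,
    max_categories: int = 3,
) -> NetworkStructure:
    """Random small time-sliced network for property testing.

    Draws a random slice layout (always one OUTCOME, optionally a MESSAGE
    node) and random arcs consistent with the slice order.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    with_message = n_nodes >= 3 and rng.random() < 0.7
    n_rest = n_nodes - 1 - int(with_message)
    slices = []
    for _ in range(n_rest):
        slices.append("T1" if rng.random() < 0.6 else "T2")
    variables = []
    for i, s in enumerate(slices):
        k = int(rng.integers(2, max_categories + 1))
        variables.append(VariableSpec(f"v{i}", s, tuple(f"c{j}" for j in range(k))))
    if with_message:
        variables.append(VariableSpec("msg", "MESSAGE", FRAMINGS))
    k = int(rng.integers(2, max_categories + 1))
    variables.append(VariableSpec("target", "OUTCOME", tuple(f"z{j}" for j in range(k))))

    order = {"T1": 0, "MESSAGE": 1, "T2": 2, "OUTCOME": 3}
    arcs = []
    names = [v.name for v in variables]
    for i, vi in enumerate(variables):
        for j, vj in enumerate(variables):
            if i == j or vj.slice == "MESSAGE" or vi.slice == "OUTCOME":
                continue
            if order[vi.slice] > order[vj.slice]:
                continue
            if order[vi.slice] == order[vj.slice] and i >= j:
                continue  # same-slice arcs follow declaration order (acyclic)
            if rng.random() < edge_prob:
                arcs.append((names[i], names[j]))
    return NetworkStructure(variables, arcs)


def random_cpts(structure: NetworkStructure, rng: np.random.Generator, concentration: float = 1.0) -> CPTSet:
    """Dirichlet-random CPTs for a structure."""
    tables = {}
    for name in structure.names:
        k = len(structure.categories(name))
        n_cfg = int(
            np.prod([len(structure.categories(p)) for p in structure.parents(name)], dtype=int)
        )
        tables[name] = rng.dirichlet(np.full(k, concentration), size=n_cfg)
    return CPTSet(structure, tables)


# ---------------------------------------------------------------------------
# loading


def load_structure(source) -> tuple[NetworkStructure, CPTSet | None]:
    """Load a structure (and CPTs when present) from JSON or by fixture name.

    ``source`` may be the fixture name ``"figure1"`` or a path to a JSON
    document in the network schema.
    """
    if isinstance(source, str) and source == "figure1":
        return figure1_structure(), None
    with open(source, "r", encoding="utf-8") as fh:
        doc: Mapping = json.load(fh)
    structure = NetworkStructure.from_json_dict(doc)
    cpts = CPTSet.from_json_dict(doc, structure) if "cpts" in doc else None
    return structure, cpts
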