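"""Categorical time-sliced Bayesian networks with exact inference.

A network spans three instants of a two-wave randomized message study:
Time-1 psychosocial antecedents (slice ``T1``), the randomized message
framing (slice ``MESSAGE``), Time-2 message-reception variables (slice
``T2``) and the single outcome *Delta intention* (slice ``OUTCOME``).
Arcs must respect the orientation of time: a parent's slice never comes
after its child's.  The MESSAGE node is parentless (randomization) and the
outcome node is childless, which is what later licenses the causal
re-reading of the graph.

Inference is exact: unobserved variables are summed out by enumeration
after pruning barren nodes.  Networks in this problem class have around a
dozen nodes, so enumeration is both exact and fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FRAMINGS",
    "TERNARY_SCALE",
    "OUTCOME_SCALE",
    "SLICE_ORDER",
    "VariableSpec",
    "NetworkStructure",
    "CPTSet",
    "CategoricalDataset",
    "ContradictoryEvidenceError",
    "estimate_cpts",
    "joint_probability",
    "posterior_target",
    "predict_target",
    "TargetPredictor",
]

#: The four outcome-sensitivity message framings, in canonical order.
FRAMINGS: tuple[str, ...] = ("gain", "nonloss", "nongain", "loss")

#: Three-level scale used for every discretized variable except the outcome.
TERNARY_SCALE: tuple[str, ...] = ("low", "medium", "high")

#: Five-level ordered scale of the outcome (change in intention), most
#: negative first.  Ties in argmax prediction resolve toward this order.
OUTCOME_SCALE: tuple[str, ...] = (
    "high-negative",
    "low-negative",
    "neutral",
    "low-positive",
    "high-positive",
)

SLICE_ORDER: dict[str, int] = {"T1": 0, "MESSAGE": 1, "T2": 2, "OUTCOME": 3}


class ContradictoryEvidenceError(ValueError):
    """Raised when supplied evidence has probability zero under the model."""


@dataclass(frozen=True)
class VariableSpec:
    """A categorical variable tagged with its time slice.

    Parameters
    ----------
    name : str
        Variable name, unique within a network.
    slice : str
        One of ``T1``, ``MESSAGE``, ``T2``, ``OUTCOME``.
    categories : tuple of str
        Ordered category labels (at least two).
    """

    name: str
    slice: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.slice not in SLICE_ORDER:
            raise ValueError(f"unknown slice tag {self.slice!r} for {self.name!r}")
        if len(self.categories) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"duplicate categories for {self.name!r}")
        if self.slice == "MESSAGE" and len(self.categories) != 4:
            raise ValueError("MESSAGE variable must have exactly 4 categories")
        object.__setattr__(self, "categories", tuple(self.categories))


class NetworkStructure:
    """Directed acyclic graph over :class:`VariableSpec` nodes.

    Validates on construction that arcs respect time-slice order, that the
    MESSAGE node has no parents, and that the single OUTCOME node has no
    children.
    """

    def __init__(
        self,
        variables: Sequence[VariableSpec],
        arcs: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.variables: tuple[VariableSpec, ...] = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        self._by_name: dict[str, VariableSpec] = {v.name: v for v in self.variables}

        outcomes = [v.name for v in self.variables if v.slice == "OUTCOME"]
        if len(outcomes) != 1:
            raise ValueError("exactly one OUTCOME variable is required")
        self.outcome: str = outcomes[0]
        messages = [v.name for v in self.variables if v.slice == "MESSAGE"]
        if len(messages) > 1:
            raise ValueError("at most one MESSAGE variable is allowed")
        self.message: str | None = messages[0] if messages else None

        self.arcs: tuple[tuple[str, str], ...] = tuple((str(p), str(c)) for p, c in arcs)
        if len(set(self.arcs)) != len(self.arcs):
            raise ValueError("duplicate arcs")
        parents: dict[str, list[str]] = {n: [] for n in names}
        for p, c in self.arcs:
            if p not in self._by_name or c not in self._by_name:
                raise ValueError(f"arc ({p!r}, {c!r}) references unknown variable")
            if SLICE_ORDER[self._by_name[p].slice] > SLICE_ORDER[self._by_name[c].slice]:
                raise ValueError(f"arc ({p!r}, {c!r}) violates time orientation")
            if self._by_name[c].slice == "MESSAGE":
                raise ValueError("MESSAGE node must be parentless (randomized)")
            if self._by_name[p].slice == "OUTCOME":
                raise ValueError("OUTCOME node must have no children")
            parents[c].append(p)
        self._parents: dict[str, tuple[str, ...]] = {n: tuple(ps) for n, ps in parents.items()}

        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(self.arcs)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structure contains a directed cycle")
        self.graph: nx.DiGraph = g

    # -- accessors ---------------------------------------------------------

    def spec(self, name: str) -> VariableSpec:
        return self._by_name[name]

    def parents(self, name: str) -> tuple[str, ...]:
        """Parents of ``name`` in arc-declaration order."""
        return self._parents[name]

    def children(self, name: str) -> tuple[str, ...]:
        return tuple(self.graph.successors(name))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def slice_variables(self, slice_tag: str) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.slice == slice_tag)

    @property
    def t1_variables(self) -> tuple[str, ...]:
        return self.slice_variables("T1")

    @property
    def t2_variables(self) -> tuple[str, ...]:
        return self.slice_variables("T2")

    def categories(self, name: str) -> tuple[str, ...]:
        return self._by_name[name].categories

    def topological_order(self) -> list[str]:
        order = {n: i for i, n in enumerate(self.names)}
        return list(nx.lexicographical_topological_sort(self.graph, key=order.get))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkStructure):
            return NotImplemented
        return self.variables == other.variables and sorted(self.arcs) == sorted(other.arcs)

    def __hash__(self) -> int:
        return hash((self.variables, tuple(sorted(self.arcs))))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"NetworkStructure({len(self.variables)} variables, {len(self.arcs)} arcs)"

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "variables": [
                {"name": v.name, "slice": v.slice, "categories": list(v.categories)}
                for v in self.variables
            ],
            "arcs": [list(a) for a in self.arcs],
        }

    @classmethod
    def from_json_dict(cls, doc: Mapping) -> "NetworkStructure":
        variables = [
            VariableSpec(d["name"], d["slice"], tuple(d["categories"]))
            for d in doc["variables"]
        ]
        return cls(variables, [tuple(a) for a in doc["arcs"]])


class CPTSet:
    """Conditional probability tables for every node of a structure.

    Tables are dense arrays of shape ``(n_parent_configs, n_categories)``;
    the parent configuration index is a mixed-radix code over the parents
    in declared order (first parent most significant).
    """

    def __init__(self, structure: NetworkStructure, tables: Mapping[str, np.ndarray], alpha: float = 0.0):
        self.structure = structure
        self.alpha = float(alpha)
        self.tables: dict[str, np.ndarray] = {}
        for name in structure.names:
            t = np.asarray(tables[name], dtype=float)
            n_cfg = int(np.prod([len(structure.categories(p)) for p in structure.parents(name)], dtype=int))
            k = len(structure.categories(name))
            if t.shape != (n_cfg, k):
                raise ValueError(f"CPT for {name!r} has shape {t.shape}, expected {(n_cfg, k)}")
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {name!r} do not sum to 1")
            if (t < 0).any():
                raise ValueError(f"negative probabilities in CPT for {name!r}")
            self.tables[name] = t

    def config_index(self, name: str, assignment: Mapping[str, str]) -> int:
        """Mixed-radix row index of the parent configuration in ``assignment``."""
        idx = 0
        for p in self.structure.parents(name):
            cats = self.structure.categories(p)
            idx = idx * len(cats) + cats.index(assignment[p])
        return idx

    def prob(self, name: str, value: str, assignment: Mapping[str, str]) -> float:
        """``p(name = value | parents as in assignment)``."""
        row = self.tables[name][self.config_index(name, assignment)]
        return float(row[self.structure.categories(name).index(value)])

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        doc = self.structure.to_json_dict()
        cpts: dict[str, dict[str, list[float]]] = {}
        for name in self.structure.names:
            parents = self.structure.parents(name)
            cat_lists = [self.structure.categories(p) for p in parents]
            rows = {}
            for i, combo in enumerate(product(*cat_lists)):
                rows["|".join(combo)] = [float(x) for x in self.tables[name][i]]
            cpts[name] = rows
        doc["cpts"] = cpts
        return doc

    @classmethod
    def from_json_dict(cls, doc: Mapping, structure: NetworkStructure | None = None) -> "CPTSet":
        structure = structure or NetworkStructure.from_json_dict(doc)
        tables = {}
        for name in structure.names:
            parents = structure.parents(name)
            cat_lists = [structure.categories(p) for p in parents]
            n_cfg = int(np.prod([len(c) for c in cat_lists], dtype=int))
            t = np.empty((n_cfg, len(structure.categories(name))))
            rows = doc["cpts"][name]
            for i, combo in enumerate(product(*cat_lists)):
                t[i] = rows["|".join(combo)]
            tables[name] = t
        return cls(structure, tables)


def save_network(path, structure: NetworkStructure, cpts: CPTSet | None = None) -> None:
    doc = cpts.to_json_dict() if cpts is not None else structure.to_json_dict()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


@dataclass
class CategoricalDataset:
    """Complete-case categorical data aligned with a network structure."""

    structure: NetworkStructure
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [n for n in self.structure.names if n not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset lacks columns {missing}")
        if self.frame[list(self.structure.names)].isna().any().any():
            raise ValueError("dataset contains missing cells")
        for name in self.structure.names:
            bad = set(self.frame[name]) - set(self.structure.categories(name))
            if bad:
                raise ValueError(f"column {name!r} has undeclared labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    def codes(self, name: str) -> np.ndarray:
        """Integer codes of a column under the declared category order."""
        cats = self.structure.categories(name)
        mapping = {c: i for i, c in enumerate(cats)}
        return self.frame[name].map(mapping).to_numpy(dtype=np.int64)


# ---------------------------------------------------------------------------
# parameter learning


def estimate_cpts(structure: NetworkStructure, data: CategoricalDataset, alpha: float = 1.0) -> CPTSet:
    """Estimate all conditional probability tables by smoothed counting.

    Each row of a table is ``(count + alpha) / (row_total + alpha * K)``
    with ``K`` the number of categories of the node (Laplace/Lidstone
    smoothing).  ``alpha = 0`` is permitted only when every parent
    configuration has support in the data.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    counts = count_tables(structure, data)
    tables = {}
    for name, c in counts.items():
        k = c.shape[1]
        tot = c.sum(axis=1, keepdims=True)
        if alpha == 0 and (tot == 0).any():
            raise ValueError(
                f"node {name!r} has parent configurations with no support; "
                "use alpha > 0"
            )
        tables[name] = (c + alpha) / (tot + alpha * k)
    return CPTSet(structure, tables, alpha=alpha)


def count_tables(structure: NetworkStructure, data: CategoricalDataset) -> dict[str, np.ndarray]:
    """Raw joint counts per node: shape ``(n_parent_configs, n_categories)``."""
    out = {}
    code_cache = {n: data.codes(n) for n in structure.names}
    for name in structure.names:
        parents = structure.parents(name)
        cards = [len(structure.categories(p)) for p in parents]
        cfg = np.zeros(len(data), dtype=np.int64)
        for p, card in zip(parents, cards):
            cfg = cfg * card + code_cache[p]
        k = len(structure.categories(name))
        n_cfg = int(np.prod(cards, dtype=int)) if cards else 1
        flat = np.bincount(cfg * k + code_cache[name], minlength=n_cfg * k)
        out[name] = flat.reshape(n_cfg, k).astype(float)
    return out


# ---------------------------------------------------------------------------
# exact inference


def joint_probability(structure: NetworkStructure, cpts: CPTSet, assignment: Mapping[str, str]) -> float:
    """Probability of a complete assignment under the factorized model."""
    missing = set(structure.names) - set(assignment)
    if missing:
        raise ValueError(f"assignment incomplete, missing {sorted(missing)}")
    p = 1.0
    for name in structure.names:
        p *= cpts.prob(name, assignment[name], assignment)
    return p


def _active_nodes(structure: NetworkStructure, target: str, evidence_vars: Iterable[str]) -> list[str]:
    """Nodes whose factors matter for ``p(target | evidence)``.

    Hidden barren nodes (no kept descendant) integrate to one and are
    dropped: only the kept nodes and their ancestors remain.  Evidence
    factors whose parents are all observed are constant in the query and
    cancel on normalization; they are pruned later.
    """
    keep = set(evidence_vars) | {target}
    active = set()
    for node in keep:
        active |= nx.ancestors(structure.graph, node) | {node}
    return [n for n in structure.topological_order() if n in active]


class TargetPredictor:
    """Reusable exact posterior of one target given a fixed evidence roster.

    Precomputes the active node set and factor list once, then answers
    posterior queries for many evidence assignments (used heavily when
    profiling the enumerated population).
    """

    def __init__(self, structure: NetworkStructure, cpts: CPTSet, target: str, evidence_vars: Sequence[str]):
        if target in evidence_vars:
            raise ValueError("target cannot be part of the evidence")
        self.structure = structure
        self.cpts = cpts
        self.target = target
        self.evidence_vars = tuple(evidence_vars)
        self.order = _active_nodes(structure, target, evidence_vars)
        known = set(self.evidence_vars) | {target}
        self.hidden = [n for n in self.order if n not in known]
        self.k = len(structure.categories(target))
        # a factor is constant (and cancels) iff the node and all its parents
        # are observed evidence
        free = set(self.hidden) | {target}
        self._factors = [
            n
            for n in self.order
            if n in free or any(p in free for p in structure.parents(n))
        ]
        # fully-observed evidence factors are constant in the query and cancel
        # on normalization -- except when one is zero, which flags
        # contradictory evidence and must still be detected
        self._constant_factors = [n for n in self.order if n not in self._factors]

    def posterior(self, evidence: Mapping[str, str]) -> np.ndarray:
        """Posterior distribution of the target given the evidence values."""
        structure, cpts = self.structure, self.cpts
        t_cats = structure.categories(self.target)
        hidden_cats = [structure.categories(h) for h in self.hidden]
        out = np.zeros(self.k)
        assignment = dict(evidence)
        for n in self._constant_factors:
            if cpts.prob(n, assignment[n], assignment) == 0.0:
                raise ContradictoryEvidenceError(
                    f"evidence {dict(evidence)!r} has probability zero under the model"
                )
        for hidden_combo in product(*hidden_cats):
            assignment.update(zip(self.hidden, hidden_combo))
            for zi, z in enumerate(t_cats):
                assignment[self.target] = z
                w = 1.0
                for n in self._factors:
                    w *= cpts.prob(n, assignment[n], assignment)
                    if w == 0.0:
                        break
                out[zi] += w
            del assignment[self.target]
        total = out.sum()
        if total <= 0.0:
            raise ContradictoryEvidenceError(
                f"evidence {dict(evidence)!r} has probability zero under the model"
            )
        return out / total


def posterior_target(
    structure: NetworkStructure,
    cpts: CPTSet,
    observations: Mapping[str, str] | None = None,
    message: str | None = None,
) -> np.ndarray:
    """Exact posterior of the outcome given partial evidence and a framing.

    Parameters
    ----------
    observations : mapping
        Partial assignment of non-outcome variables to category labels.
    message : str, optional
        Framing label for the MESSAGE node; required when the structure has
        a MESSAGE node and it is not already in ``observations``.

    Returns
    -------
    ndarray
        Probability vector over the outcome's categories (sums to one).
    """
    observations = dict(observations or {})
    if structure.outcome in observations:
        raise ValueError("the outcome variable cannot be observed")
    if message is not None:
        if structure.message is None:
            raise ValueError("structure has no MESSAGE node")
        if message not in structure.categories(structure.message):
            raise ValueError(f"unknown framing {message!r}")
        observations[structure.message] = message
    for var, val in observations.items():
        if val not in structure.categories(var):
            raise ValueError(f"label {val!r} not declared for {var!r}")
    predictor = TargetPredictor(structure, cpts, structure.outcome, tuple(observations))
    return predictor.posterior(observations)


def predict_target(
    structure: NetworkStructure,
    cpts: CPTSet,
    observations: Mapping[str, str] | None = None,
    message: str | None = None,
) -> str:
    """Modal outcome category; ties resolve toward the earlier category."""
    post = posterior_target(structure, cpts, observations, message)
    return structure.categories(structure.outcome)[int(np.argmax(post))]
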