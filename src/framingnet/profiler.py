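"""Exhaustive simulated-population profiling and receiver prototypes.

The fitted causal model is interrogated by enumerating one individual per
possible Time-1 configuration (3^8 = 6561 for the published structure),
attaching to each the four-dimensional vector of framing effects
``(e_gain, e_nonloss, e_nongain, e_loss)``, and treating that vector as a
soft clustering profile under Euclidean dissimilarity.  A 2-D t-SNE
embedding serves visualization; prototype groups are cut at a quantile of
the relevant summary:

* per framing: the top ``ceil(q N)`` individuals by best effect among
  those whose best framing is that framing,
* *indifferent*: the bottom ``ceil(q N)`` by delta effect (equally
  persuaded by all framings),
* *oppositive*: the bottom ``ceil(q N)`` by mean effect (negative
  expected response to every framing).

Each group is summarized by the modal category of a small set of
reporting antecedents (default: baseline intention, prevention focus,
perceived severity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .causal import EffectVector, UtilityWeights, effect_vector
from .network import CPTSet, NetworkStructure, TargetPredictor

__all__ = [
    "enumerate_population",
    "profile_population",
    "population_frame",
    "dissimilarity",
    "embed_population",
    "PrototypeReport",
    "extract_prototypes",
    "DEFAULT_REPORT_DIMENSIONS",
]

DEFAULT_REPORT_DIMENSIONS: tuple[str, ...] = (
    "baseline_intention",
    "prevention_focus",
    "perceived_severity",
)


def enumerate_population(structure: NetworkStructure) -> list[dict[str, str]]:
    """One individual per Time-1 configuration, in lexicographic order.

    Order is the Cartesian product of declared category lists over the
    Time-1 variables in declaration order; with no Time-1 variables the
    population is the single empty profile.
    """
    t1 = structure.t1_variables
    cat_lists = [structure.categories(v) for v in t1]
    return [dict(zip(t1, combo)) for combo in product(*cat_lists)]


def profile_population(
    structure: NetworkStructure,
    cpts: CPTSet,
    weights: UtilityWeights | None = None,
) -> list[EffectVector]:
    """Effect vector of every enumerated individual, in enumeration order."""
    weights = weights or UtilityWeights()
    t1 = structure.t1_variables
    predictor = TargetPredictor(structure, cpts, structure.outcome, (*t1, structure.message))
    return [
        effect_vector(structure, cpts, ind, weights, _predictor=predictor)
        for ind in enumerate_population(structure)
    ]


def population_frame(vectors: Sequence[EffectVector]) -> pd.DataFrame:
    """Tabular view: Time-1 assignment, four effects, summaries, best framing."""
    rows = []
    for v in vectors:
        row = dict(v.t1_assignment)
        row.update(v.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def dissimilarity(v1: EffectVector, v2: EffectVector) -> float:
    """Euclidean distance between two 4-D effect vectors."""
    return float(np.linalg.norm(np.asarray(v1.effects) - np.asarray(v2.effects)))


def embed_population(
    vectors: Sequence[EffectVector] | np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """2-D t-SNE embedding of the effect vectors (visualization only)."""
    x = (
        np.asarray([v.effects for v in vectors], dtype=float)
        if not isinstance(vectors, np.ndarray)
        else np.asarray(vectors, dtype=float)
    )
    if x.shape[0] < 2:
        raise ValueError("need at least 2 individuals to embed")
    if np.allclose(x, x[0]):
        warnings.warn("all effect vectors identical; jittering before embedding", stacklevel=2)
        x = x + np.random.default_rng(seed).normal(scale=1e-6, size=x.shape)
    from sklearn.manifold import TSNE

    perplexity = min(perplexity, (x.shape[0] - 1) / 3)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
    )
    return tsne.fit_transform(x)


@dataclass(frozen=True)
class PrototypeReport:
    """A quantile-cut receiver group with its modal antecedent profile."""

    criterion: str  # best-gain / best-nonloss / best-nongain / best-loss / indifferent / oppositive
    indices: tuple[int, ...]
    modal_profile: Mapping[str, str]
    assigned_framing: str | None  # None for indifferent / oppositive

    @property
    def size(self) -> int:
        return len(self.indices)


def _modal_profile(
    vectors: Sequence[EffectVector],
    indices: Sequence[int],
    dims: Sequence[str],
    structure: NetworkStructure,
) -> dict[str, str]:
    profile = {}
    for dim in dims:
        cats = structure.categories(dim)
        counts = {c: 0 for c in cats}
        for i in indices:
            counts[dict(vectors[i].t1_assignment)[dim]] += 1
        profile[dim] = max(cats, key=lambda c: (counts[c], -cats.index(c)))
    return profile


def extract_prototypes(
    vectors: Sequence[EffectVector],
    structure: NetworkStructure,
    q: float = 0.02,
    report_dimensions: Sequence[str] = DEFAULT_REPORT_DIMENSIONS,
    restrict_to_best: bool = True,
) -> list[PrototypeReport]:
    """Six quantile-cut prototype groups from a profiled population.

    ``q`` is the quantile fraction; each group holds ``ceil(q N)``
    individuals (rank ties resolve by enumeration order).  With
    ``restrict_to_best`` (default) the per-framing pools only contain
    individuals whose pivot framing is that framing.
    """
    n = len(vectors)
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    k = math.ceil(q * n)
    if k < 1:
        raise ValueError("q * N < 1: no individuals to select")
    for dim in report_dimensions:
        if dim not in structure.t1_variables:
            raise ValueError(f"reporting dimension {dim!r} is not a Time-1 variable")
    best = np.array([v.best_effect for v in vectors])
    delta = np.array([v.delta_effect for v in vectors])
    mean = np.array([v.mean_effect for v in vectors])
    best_framing = np.array([v.best_framing for v in vectors], dtype=object)

    reports = []
    framings = structure.categories(structure.message)
    for f in framings:
        pool = (
            np.flatnonzero(best_framing == f)
            if restrict_to_best
            else np.arange(n)
        )
        order = pool[np.argsort(-best[pool], kind="stable")]
        idx = tuple(int(i) for i in order[:k])
        reports.append(
            PrototypeReport(
                criterion=f"best-{f}",
                indices=idx,
                modal_profile=_modal_profile(vectors, idx, report_dimensions, structure),
                assigned_framing=f,
            )
        )
    for crit, score in (("indifferent", delta), ("oppositive", mean)):
        order = np.argsort(score, kind="stable")
        idx = tuple(int(i) for i in order[:k])
        reports.append(
            PrototypeReport(
                criterion=crit,
                indices=idx,
                modal_profile=_modal_profile(vectors, idx, report_dimensions, structure),
                assigned_framing=None,
            )
        )
    return reports
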