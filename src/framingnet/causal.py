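"""Causal reading of the elicited network: utilities and potential effects.

Because the message node is randomized (parentless), the Time-1
antecedents form a valid adjustment set: every back-door path between the
message and the outcome is blocked, and the interventional distribution
``p(Z | do(m), T1)`` coincides with the conditional ``p(Z | m, T1)``.

The outcome distribution is summarized by a utility: ordered weights
``(2, 1, 0, -1, -2)`` over ``(high-positive, ..., high-negative)`` change
in intention, applied exactly as published.  Note a *positive* change
means *increased* meat intention, so campaigns aiming at reduction may
prefer the negated convention; the ``negate`` flag flips every effect's
sign exactly.

The *average potential effect* (APE) of a framing ``m`` is the expected
utility under ``do(m)`` given the observed antecedents.  With a partial
Time-1 observation the unobserved antecedents are marginalized out under
their learned joint marginal ``p(T1_n)`` (back-door adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .network import (
    OUTCOME_SCALE,
    CPTSet,
    NetworkStructure,
    TargetPredictor,
    posterior_target,
)

__all__ = ["UtilityWeights", "EffectVector", "utility", "ape", "effect_vector"]

_DEFAULT_WEIGHTS = {
    "high-positive": 2.0,
    "low-positive": 1.0,
    "neutral": 0.0,
    "low-negative": -1.0,
    "high-negative": -2.0,
}


@dataclass(frozen=True)
class UtilityWeights:
    """Ordered weights over the outcome scale, optionally sign-flipped."""

    weights: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    negate: bool = False

    def vector(self, categories: Sequence[str]) -> np.ndarray:
        try:
            w = np.array([self.weights[c] for c in categories], dtype=float)
        except KeyError as exc:
            raise ValueError(f"no utility weight for category {exc.args[0]!r}") from None
        diffs = np.diff(w)
        if not ((diffs > 0).all() or (diffs < 0).all()):
            raise ValueError("utility weights must be strictly monotone over the ordered scale")
        return -w if self.negate else w


def utility(dist, weights: UtilityWeights | None = None, categories: Sequence[str] = OUTCOME_SCALE) -> float:
    """Expected utility ``sum_z w(z) p(z)`` of an outcome distribution."""
    weights = weights or UtilityWeights()
    p = np.asarray(dist, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("distribution must sum to 1")
    if len(p) != len(categories):
        raise ValueError("distribution length does not match the category list")
    return float(weights.vector(categories) @ p)


def _t1_marginal(
    structure: NetworkStructure, cpts: CPTSet, hidden: Sequence[str]
) -> dict[tuple[str, ...], float]:
    """Joint marginal ``p(T1_n)`` of the unobserved Time-1 variables."""
    t1 = structure.t1_variables
    order = [v for v in structure.topological_order() if v in set(t1)]
    out: dict[tuple[str, ...], float] = {}
    for combo in product(*[structure.categories(v) for v in order]):
        assignment = dict(zip(order, combo))
        p = 1.0
        for v in order:
            p *= cpts.prob(v, assignment[v], assignment)
        key = tuple(assignment[h] for h in hidden)
        out[key] = out.get(key, 0.0) + p
    return out


def ape(
    structure: NetworkStructure,
    cpts: CPTSet,
    m: str,
    t1_observed: Mapping[str, str],
    weights: UtilityWeights | None = None,
) -> float:
    """Average potential effect of framing ``m`` given observed antecedents.

    ``t1_observed`` maps a subset of the Time-1 variables to labels; any
    other supplied variable (Time-2 or outcome) is rejected because it lies
    on the indirect causal path and would bias the adjustment.  Unobserved
    Time-1 variables are marginalized under their learned joint marginal.
    """
    weights = weights or UtilityWeights()
    if structure.message is None:
        raise ValueError("structure has no MESSAGE node to intervene on")
    t1 = set(structure.t1_variables)
    bad = [v for v in t1_observed if v not in t1]
    if bad:
        raise ValueError(
            f"only Time-1 antecedents may be observed for the adjustment; got {bad}"
        )
    hidden = [v for v in structure.t1_variables if v not in t1_observed]
    cats = structure.categories(structure.outcome)
    if not hidden:
        post = posterior_target(structure, cpts, dict(t1_observed), message=m)
        return utility(post, weights, cats)
    marginal = _t1_marginal(structure, cpts, hidden)
    total = 0.0
    for combo, p_hidden in marginal.items():
        if p_hidden == 0.0:
            continue
        obs = dict(t1_observed)
        obs.update(zip(hidden, combo))
        post = posterior_target(structure, cpts, obs, message=m)
        total += p_hidden * utility(post, weights, cats)
    return total


@dataclass(frozen=True)
class EffectVector:
    """Per-individual potential effects of the four framings."""

    t1_assignment: tuple[tuple[str, str], ...]
    effects: tuple[float, ...]  # ordered as the MESSAGE node's categories
    framings: tuple[str, ...]

    @property
    def mean_effect(self) -> float:
        return float(np.mean(self.effects))

    @property
    def best_effect(self) -> float:
        return float(np.max(self.effects))

    @property
    def delta_effect(self) -> float:
        return self.best_effect - self.mean_effect

    @property
    def best_framing(self) -> str:
        """Framing with the maximal effect; ties resolve by declared order."""
        return self.framings[int(np.argmax(self.effects))]

    def as_dict(self) -> dict[str, float | str]:
        d: dict[str, float | str] = {f"e_{f}": e for f, e in zip(self.framings, self.effects)}
        d["mean_effect"] = self.mean_effect
        d["best_effect"] = self.best_effect
        d["delta_effect"] = self.delta_effect
        d["best_framing"] = self.best_framing
        return d


def effect_vector(
    structure: NetworkStructure,
    cpts: CPTSet,
    t1_assignment: Mapping[str, str],
    weights: UtilityWeights | None = None,
    _predictor: TargetPredictor | None = None,
) -> EffectVector:
    """APE under every framing for a fully observed Time-1 profile."""
    weights = weights or UtilityWeights()
    t1 = structure.t1_variables
    missing = [v for v in t1 if v not in t1_assignment]
    if missing:
        raise ValueError(f"full Time-1 assignment required; missing {missing}")
    framings = structure.categories(structure.message)
    cats = structure.categories(structure.outcome)
    if _predictor is None:
        _predictor = TargetPredictor(
            structure, cpts, structure.outcome, (*t1, structure.message)
        )
    effects = []
    evidence = {v: t1_assignment[v] for v in t1}
    for m in framings:
        evidence[structure.message] = m
        effects.append(utility(_predictor.posterior(evidence), weights, cats))
    return EffectVector(
        t1_assignment=tuple((v, t1_assignment[v]) for v in t1),
        effects=tuple(effects),
        framings=tuple(framings),
    )
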