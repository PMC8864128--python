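"""statsmodels-style entry point: ``FramingDBN`` and ``FramingDBNResults``.

``FramingDBN`` wraps a categorical dataset plus either a known network
structure or the settings for automated elicitation; ``fit`` learns the
conditional probability tables (and, when requested, the structure) and
returns a results object carrying the estimates, the in-sample and
leave-one-out multiclass AUC diagnostics, and the downstream causal and
profiling queries.

Typical use::

    from framingnet import FramingDBN, figure1_structure

    model = FramingDBN.from_cohort(cohort_df)          # discretizes scores
    res = model.fit(alpha=1.0)                         # elicits + trains
    print(res.summary())
    res.ape("loss", {"baseline_intention": "high", ...})
    res.prototypes()
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import search as _search
from .causal import EffectVector, UtilityWeights, ape as _ape, effect_vector as _effect_vector
from .discretize import DiscretizationMap, apply_map, fit_map
from .fixtures import DIRECT_MODERATORS, MEDIATED_ANTECEDENTS
from .network import (
    FRAMINGS,
    CategoricalDataset,
    CPTSet,
    NetworkStructure,
    VariableSpec,
    estimate_cpts,
    posterior_target,
    predict_target,
)
from .profiler import (
    DEFAULT_REPORT_DIMENSIONS,
    PrototypeReport,
    embed_population,
    enumerate_population,
    extract_prototypes,
    population_frame,
    profile_population,
)

__all__ = ["FramingDBN", "FramingDBNResults"]


@dataclass
class SearchSettings:
    max_parents_outcome: int = 6
    max_parents_t2: int = 5
    top_k: int = 3
    allow_intra_t2: bool = False


class FramingDBN:
    """Categorical time-sliced Bayesian network model of a framing study."""

    def __init__(
        self,
        data: CategoricalDataset,
        structure: NetworkStructure | None = None,
        search: SearchSettings | None = None,
    ):
        self.data = data
        self.structure = structure
        self.search = search or SearchSettings()

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        t1_variables: Sequence[str] = DIRECT_MODERATORS + MEDIATED_ANTECEDENTS,
        t2_variables: Sequence[str] = ("systematic_processing",),
        condition: str = "condition",
        outcome: str = "delta_intention",
        structure: NetworkStructure | None = None,
        search: SearchSettings | None = None,
        dmap: DiscretizationMap | None = None,
    ) -> "FramingDBN":
        """Build the model from a continuous cohort table.

        Scale scores are discretized by 33% quantiles (20% quantiles for
        the outcome) unless a pre-fitted :class:`DiscretizationMap` is
        supplied.  The variable roster defaults to the published model's
        eight antecedents plus systematic processing.
        """
        cols = [*t1_variables, *t2_variables, outcome]
        if dmap is None:
            dmap = fit_map(cohort[cols], outcome=outcome)
        table = apply_map(cohort[cols], dmap)
        table[condition] = cohort[condition].to_numpy()
        variables = [VariableSpec(v, "T1", dmap.entries[v].labels) for v in t1_variables]
        variables.append(VariableSpec(condition, "MESSAGE", tuple(sorted(set(table[condition]), key=list(FRAMINGS).index))))
        variables += [VariableSpec(v, "T2", dmap.entries[v].labels) for v in t2_variables]
        variables.append(VariableSpec(outcome, "OUTCOME", dmap.entries[outcome].labels))
        roster = NetworkStructure(variables, structure.arcs if structure else ())
        model = cls(CategoricalDataset(roster, table), structure=structure, search=search)
        model.dmap = dmap
        return model

    def fit(self, alpha: float = 1.0, elicit: bool | None = None) -> "FramingDBNResults":
        """Learn structure (optionally) and parameters; return results.

        ``elicit`` defaults to True when no structure was supplied.
        """
        if elicit is None:
            elicit = self.structure is None
        report = candidates = None
        if elicit:
            best, report, candidates = _search.elicit_structure(
                self.data,
                max_parents_outcome=self.search.max_parents_outcome,
                max_parents_t2=self.search.max_parents_t2,
                top_k=self.search.top_k,
                alpha=alpha,
                allow_intra_t2=self.search.allow_intra_t2,
            )
            structure = best.structure
        elif self.structure is not None:
            structure = NetworkStructure(self.data.structure.variables, self.structure.arcs)
        else:
            raise ValueError("no structure supplied and elicitation disabled")
        data = CategoricalDataset(structure, self.data.frame)
        cpts = estimate_cpts(structure, data, alpha=alpha)
        return FramingDBNResults(
            model=self,
            structure=structure,
            cpts=cpts,
            alpha=alpha,
            screening=report,
            candidates=candidates,
        )


class FramingDBNResults:
    """Fitted network with diagnostics and causal/profiling queries."""

    def __init__(self, model, structure, cpts, alpha, screening=None, candidates=None):
        self.model = model
        self.structure: NetworkStructure = structure
        self.cpts: CPTSet = cpts
        self.alpha = alpha
        self.screening = screening
        self.candidates = candidates
        self._data = CategoricalDataset(structure, model.data.frame)
        self._mauc_in: float | None = None
        self._mauc_loo: float | None = None

    # -- diagnostics -------------------------------------------------------

    @property
    def mauc_in(self) -> float:
        """In-sample Hand-Till multiclass AUC of the outcome predictions."""
        if self._mauc_in is None:
            self._mauc_in = _search.in_sample_mauc(self.structure, self._data, self.alpha)
        return self._mauc_in

    @property
    def mauc_loo(self) -> float:
        """Leave-one-out Hand-Till multiclass AUC."""
        if self._mauc_loo is None:
            self._mauc_loo = _search.loo_mauc(self.structure, self._data, self.alpha)
        return self._mauc_loo

    def summary(self) -> str:
        """Human-readable fit report."""
        s = self.structure
        lines = [
            "Framing-study categorical DBN",
            "=" * 34,
            f"records:            {len(self._data)}",
            f"variables:          {len(s.variables)} "
            f"(T1={len(s.t1_variables)}, T2={len(s.t2_variables)})",
            f"arcs:               {len(s.arcs)}",
            f"smoothing alpha:    {self.alpha}",
            f"mAUC (in-sample):   {self.mauc_in:.4f}",
            f"mAUC (leave-1-out): {self.mauc_loo:.4f}",
            "",
            "parent sets",
            "-" * 34,
        ]
        for v in s.names:
            ps = s.parents(v)
            if ps:
                lines.append(f"{v} <- {', '.join(ps)}")
        return "\n".join(lines)

    # -- prediction and causal queries ------------------------------------

    def predict_distribution(self, observations: Mapping[str, str], message: str) -> np.ndarray:
        return posterior_target(self.structure, self.cpts, observations, message)

    def predict(self, observations: Mapping[str, str], message: str) -> str:
        return predict_target(self.structure, self.cpts, observations, message)

    def ape(
        self,
        message: str,
        t1_observed: Mapping[str, str],
        weights: UtilityWeights | None = None,
    ) -> float:
        """Average potential effect of a framing given Time-1 observations."""
        return _ape(self.structure, self.cpts, message, t1_observed, weights)

    def effect_vector(self, t1_assignment: Mapping[str, str], weights=None) -> EffectVector:
        return _effect_vector(self.structure, self.cpts, t1_assignment, weights)

    # -- population profiling ----------------------------------------------

    def population(self, weights: UtilityWeights | None = None) -> pd.DataFrame:
        """Fully enumerated simulated population with effect summaries."""
        return population_frame(profile_population(self.structure, self.cpts, weights))

    def prototypes(
        self,
        q: float = 0.02,
        report_dimensions: Sequence[str] = DEFAULT_REPORT_DIMENSIONS,
        weights: UtilityWeights | None = None,
    ) -> list[PrototypeReport]:
        vectors = profile_population(self.structure, self.cpts, weights)
        return extract_prototypes(vectors, self.structure, q, report_dimensions)

    def embedding(self, perplexity: float = 30.0, seed: int = 0, weights=None) -> np.ndarray:
        vectors = profile_population(self.structure, self.cpts, weights)
        return embed_population(vectors, perplexity=perplexity, seed=seed)

    def plot_population(self, color: str = "best_framing", perplexity: float = 30.0, seed: int = 0, ax=None):
        """Scatter the t-SNE embedding colored by an effect summary.

        ``color`` is one of ``mean_effect``, ``best_effect``,
        ``delta_effect`` or ``best_framing``.
        """
        import matplotlib.pyplot as plt

        frame = self.population()
        coords = embed_population(
            frame[[c for c in frame.columns if c.startswith("e_")]].to_numpy(),
            perplexity=perplexity,
            seed=seed,
        )
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        if color == "best_framing":
            for framing in self.structure.categories(self.structure.message):
                mask = frame["best_framing"] == framing
                ax.scatter(coords[mask, 0], coords[mask, 1], s=4, label=framing)
            ax.legend(title="best framing", fontsize=8)
        else:
            sc = ax.scatter(coords[:, 0], coords[:, 1], s=4, c=frame[color], cmap="coolwarm")
            ax.figure.colorbar(sc, ax=ax, label=color)
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        ax.set_title(f"Simulated population ({color})")
        return ax
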