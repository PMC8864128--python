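"""Automated elicitation of the network structure.

The search mirrors the study's two-stage procedure:

1. *Screening.*  Proceeding backward from the outcome, candidate parent
   sets for the outcome and for each Time-2 node are enumerated (up to a
   size cap) and ranked by empirical information gain
   ``IG(X; S) = H(X) - H(X | S)``.  Note the source formulation prints the
   difference with the opposite sign; the non-negative convention is used
   here, and rankings are identical either way by magnitude.
2. *Selection.*  The retained parent sets are crossed into candidate
   structures.  Each candidate is scored by the sum of its in-sample and
   leave-one-out multiclass AUC (Hand-Till M measure), each normalized by
   the pool maximum:

   ``m = mAUC_in / max(mAUC_in) + mAUC_out / max(mAUC_out)``

   and the candidate with the highest ``m`` wins.

Leave-one-out refits are performed incrementally (subtracting the held-out
record's sufficient statistics), which makes the n refits per candidate
cost the same as one vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .network import (
    SLICE_ORDER,
    CategoricalDataset,
    NetworkStructure,
    count_tables,
    estimate_cpts,
)

__all__ = [
    "ScreeningEntry",
    "ScreeningReport",
    "CandidateStructure",
    "entropy",
    "conditional_entropy",
    "information_gain",
    "screen_parent_sets",
    "enumerate_candidates",
    "binary_auc",
    "mauc",
    "in_sample_mauc",
    "loo_mauc",
    "select_structure",
    "elicit_structure",
]


# ---------------------------------------------------------------------------
# empirical information measures


def _joint_codes(data: CategoricalDataset, names: Sequence[str]) -> tuple[np.ndarray, int]:
    cfg = np.zeros(len(data), dtype=np.int64)
    n_cfg = 1
    for n in names:
        card = len(data.structure.categories(n))
        cfg = cfg * card + data.codes(n)
        n_cfg *= card
    return cfg, n_cfg


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def entropy(name: str, data: CategoricalDataset) -> float:
    """Empirical entropy of a variable, in nats (``0 log 0 := 0``)."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    codes, n_cfg = _joint_codes(data, [name])
    return _entropy_from_counts(np.bincount(codes, minlength=n_cfg))


def conditional_entropy(name: str, parents: Iterable[str], data: CategoricalDataset) -> float:
    """Empirical conditional entropy ``H(X | parents)`` in nats."""
    parents = tuple(parents)
    if name in parents:
        raise ValueError("a variable cannot condition on itself")
    if not parents:
        return entropy(name, data)
    if len(data) == 0:
        raise ValueError("empty dataset")
    joint, n_joint = _joint_codes(data, [*parents, name])
    par, n_par = _joint_codes(data, parents)
    h_joint = _entropy_from_counts(np.bincount(joint, minlength=n_joint))
    h_par = _entropy_from_counts(np.bincount(par, minlength=n_par))
    return h_joint - h_par


def information_gain(name: str, parents: Iterable[str], data: CategoricalDataset) -> float:
    """Non-negative empirical information gain ``H(X) - H(X | parents)``."""
    return max(entropy(name, data) - conditional_entropy(name, parents, data), 0.0)


# ---------------------------------------------------------------------------
# screening


@dataclass(frozen=True)
class ScreeningEntry:
    parents: tuple[str, ...]
    entropy: float
    conditional_entropy: float
    information_gain: float


@dataclass
class ScreeningReport:
    """Ranked candidate parent sets per screened node."""

    entries: dict[str, list[ScreeningEntry]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            node: [
                {
                    "parents": list(e.parents),
                    "entropy": e.entropy,
                    "conditional_entropy": e.conditional_entropy,
                    "information_gain": e.information_gain,
                }
                for e in ranked
            ]
            for node, ranked in self.entries.items()
        }


def screen_parent_sets(
    node: str,
    allowed_parents: Iterable[str],
    data: CategoricalDataset,
    max_size: int = 5,
    top_k: int = 3,
) -> list[ScreeningEntry]:
    """Enumerate and rank candidate parent sets for one node.

    All subsets of ``allowed_parents`` up to ``max_size`` are scored by
    information gain; the ``top_k`` best are returned.  Ties break toward
    the smaller set, then lexicographically by names.
    """
    if max_size < 0:
        raise ValueError("max_size must be >= 0")
    structure = data.structure
    node_rank = SLICE_ORDER[structure.spec(node).slice]
    if structure.spec(node).slice == "MESSAGE":
        raise ValueError("the MESSAGE node is randomized and admits no parents")
    allowed = sorted(set(allowed_parents))
    for p in allowed:
        if p == node:
            raise ValueError("a node cannot be its own parent")
        spec = structure.spec(p)
        if spec.slice == "OUTCOME":
            raise ValueError("the outcome can never be a parent")
        if SLICE_ORDER[spec.slice] > node_rank:
            raise ValueError(f"{p!r} ({spec.slice}) cannot parent {node!r} (time orientation)")
    h = entropy(node, data)
    entries = []
    for size in range(0, min(max_size, len(allowed)) + 1):
        for subset in combinations(allowed, size):
            h_cond = conditional_entropy(node, subset, data)
            entries.append(
                ScreeningEntry(subset, h, h_cond, max(h - h_cond, 0.0))
            )
    entries.sort(key=lambda e: (-e.information_gain, len(e.parents), e.parents))
    return entries[:top_k]


@dataclass
class CandidateStructure:
    """A screened structure with its evaluation scores."""

    structure: NetworkStructure
    rank: int = 0
    mauc_in: float | None = None
    mauc_out: float | None = None
    m_score: float | None = None


def enumerate_candidates(
    screening: Mapping[str, Sequence[ScreeningEntry]],
    roster: NetworkStructure,
) -> list[CandidateStructure]:
    """Cross retained parent sets into valid candidate structures.

    ``roster`` supplies the variable specs; candidates combine one retained
    parent set per screened node and are filtered for acyclicity and slice
    constraints (invalid combinations, possible when intra-slice arcs are
    allowed, are dropped).
    """
    nodes = list(screening)
    if not nodes:
        raise ValueError("empty screening report")
    pools = [screening[n] for n in nodes]
    if any(len(p) == 0 for p in pools):
        raise ValueError("a screened node has no retained parent sets")
    out: list[CandidateStructure] = []
    for i, combo in enumerate(product(*pools)):
        arcs: list[tuple[str, str]] = []
        for node, entry in zip(nodes, combo):
            arcs += [(p, node) for p in entry.parents]
        try:
            out.append(CandidateStructure(NetworkStructure(roster.variables, arcs), rank=i))
        except ValueError:
            continue
    if not out:
        raise ValueError("no valid candidate structures")
    return out


# ---------------------------------------------------------------------------
# AUC metrics


def binary_auc(scores, labels) -> float:
    """Area under the ROC for binary labels; ties count half (Mann-Whitney)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def mauc(posteriors, labels) -> float:
    """Hand-Till multiclass AUC from class-posterior scores.

    ``posteriors`` is ``(n, c)`` with columns indexed by class code;
    ``labels`` are integer class codes.  Averages
    ``A(i, j) = [A(i|j) + A(j|i)] / 2`` over all unordered pairs of classes
    present in the labels.
    """
    post = np.asarray(posteriors, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    total = 0.0
    n_pairs = 0
    for a, b in combinations(classes.tolist(), 2):
        mask = (y == a) | (y == b)
        ya = y[mask] == a
        a_given_b = binary_auc(post[mask, a], ya)
        b_given_a = binary_auc(post[mask, b], ~ya)
        total += 0.5 * (a_given_b + b_given_a)
        n_pairs += 1
    return total / n_pairs


# ---------------------------------------------------------------------------
# structure evaluation (in-sample and leave-one-out posteriors)


class _OutcomeEngine:
    """Vectorized outcome posteriors given Time-1 + message evidence.

    Precomputes per-node sufficient statistics and evaluates, for every
    record at once, ``p(Z | T1, M)`` either in-sample or leave-one-out
    (by decrementing the record's own counts where the evaluated
    configuration coincides with the record's observed one).
    """

    def __init__(self, structure: NetworkStructure, data: CategoricalDataset, alpha: float):
        import networkx as nx

        self.structure = structure
        self.alpha = float(alpha)
        self.n = len(data)
        z = structure.outcome
        evidence = set(structure.t1_variables)
        if structure.message is not None:
            evidence.add(structure.message)
        anc = nx.ancestors(structure.graph, z)
        self.hidden = [v for v in structure.topological_order() if v in anc and v not in evidence]
        self.z = z
        self.k = len(structure.categories(z))
        self.counts = count_tables(structure, data)
        self.codes = {v: data.codes(v) for v in structure.names}

        self._factor_nodes = [z, *self.hidden]
        self._split: dict[str, tuple[np.ndarray, dict[str, int]]] = {}
        for node in self._factor_nodes:
            parents = structure.parents(node)
            cards = [len(structure.categories(p)) for p in parents]
            weights = np.ones(len(parents), dtype=np.int64)
            for i in range(len(parents) - 2, -1, -1):
                weights[i] = weights[i + 1] * cards[i + 1]
            cfg_e = np.zeros(self.n, dtype=np.int64)
            hidden_w: dict[str, int] = {}
            for p, w in zip(parents, weights):
                if p in self.hidden:
                    hidden_w[p] = int(w)
                else:
                    cfg_e += int(w) * self.codes[p]
            self._split[node] = (cfg_e, hidden_w)
        # the record's own (full-data) configuration per node
        self._cfg_full = {}
        for node in self._factor_nodes:
            cfg_e, hidden_w = self._split[node]
            cfg = cfg_e.copy()
            for p, w in hidden_w.items():
                cfg = cfg + w * self.codes[p]
            self._cfg_full[node] = cfg
        self._hidden_cards = [len(structure.categories(h)) for h in self.hidden]

    def posteriors(self, loo: bool) -> np.ndarray:
        """``(n, k)`` matrix of outcome posteriors for every record."""
        a = self.alpha
        n, k = self.n, self.k
        out = np.zeros((n, k))
        rows = np.arange(n)
        for combo in product(*[range(c) for c in self._hidden_cards]):
            cvals = dict(zip(self.hidden, combo))
            # outcome factor: full probability vector over z
            cfg_e, hidden_w = self._split[self.z]
            cfg = cfg_e + sum(w * cvals[p] for p, w in hidden_w.items())
            num = self.counts[self.z][cfg].copy()
            den = self.counts[self.z][cfg].sum(axis=1)
            if loo:
                own = cfg == self._cfg_full[self.z]
                num[own, self.codes[self.z][own]] -= 1.0
                den = den - own
            vec = (num + a) / (den + a * k)[:, None]
            # hidden factors
            w_all = np.ones(n)
            for h in self.hidden:
                cfg_e_h, hidden_w_h = self._split[h]
                cfg_h = cfg_e_h + sum(w * cvals[p] for p, w in hidden_w_h.items())
                kh = len(self.structure.categories(h))
                num_h = self.counts[h][cfg_h, cvals[h]]
                den_h = self.counts[h][cfg_h].sum(axis=1)
                if loo:
                    own_h = cfg_h == self._cfg_full[h]
                    num_h = num_h - (own_h & (self.codes[h] == cvals[h]))
                    den_h = den_h - own_h
                w_all *= (num_h + a) / (den_h + a * kh)
            out += w_all[:, None] * vec
        totals = out.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            raise ValueError("zero-probability evidence encountered; use alpha > 0")
        return out / totals


def in_sample_mauc(structure: NetworkStructure, data: CategoricalDataset, alpha: float = 1.0) -> float:
    """mAUC of outcome posteriors when training and scoring on all records."""
    engine = _OutcomeEngine(structure, data, alpha)
    return mauc(engine.posteriors(loo=False), data.codes(structure.outcome))


def loo_mauc(structure: NetworkStructure, data: CategoricalDataset, alpha: float = 1.0) -> float:
    """Leave-one-out mAUC: each record scored by a model fit on the rest."""
    n_classes = len(structure.categories(structure.outcome))
    if len(data) < n_classes + 1:
        raise ValueError("need at least n_classes + 1 records for leave-one-out")
    engine = _OutcomeEngine(structure, data, alpha)
    return mauc(engine.posteriors(loo=True), data.codes(structure.outcome))


def select_structure(
    candidates: Sequence[CandidateStructure],
    data: CategoricalDataset,
    alpha: float = 1.0,
) -> CandidateStructure:
    """Score every candidate and return the argmax of the combined metric.

    Each candidate's in-sample and leave-one-out mAUC are normalized by the
    pool maxima and summed; ties break toward fewer arcs, then the
    lexicographically smaller arc list.
    """
    if not candidates:
        raise ValueError("empty candidate pool")
    for cand in candidates:
        engine = _OutcomeEngine(cand.structure, data, alpha)
        y = data.codes(cand.structure.outcome)
        cand.mauc_in = mauc(engine.posteriors(loo=False), y)
        cand.mauc_out = mauc(engine.posteriors(loo=True), y)
    max_in = max(c.mauc_in for c in candidates)
    max_out = max(c.mauc_out for c in candidates)
    for cand in candidates:
        cand.m_score = (cand.mauc_in / max_in if max_in > 0 else 0.0) + (
            cand.mauc_out / max_out if max_out > 0 else 0.0
        )
    return min(
        candidates,
        key=lambda c: (-c.m_score, len(c.structure.arcs), sorted(c.structure.arcs)),
    )


def elicit_structure(
    data: CategoricalDataset,
    max_parents_outcome: int = 6,
    max_parents_t2: int = 5,
    top_k: int = 3,
    alpha: float = 1.0,
    allow_intra_t2: bool = False,
) -> tuple[CandidateStructure, ScreeningReport, list[CandidateStructure]]:
    """Full backward elicitation: screen, enumerate, select.

    The outcome is screened first (allowed parents: MESSAGE, Time-2 and
    Time-1 variables), then every Time-2 node (allowed parents: MESSAGE and
    Time-1; other Time-2 nodes only when ``allow_intra_t2``).
    """
    roster = data.structure
    report = ScreeningReport()
    z = roster.outcome
    z_allowed = list(roster.t1_variables) + list(roster.t2_variables)
    if roster.message is not None:
        z_allowed.append(roster.message)
    report.entries[z] = screen_parent_sets(z, z_allowed, data, max_parents_outcome, top_k)
    for node in roster.t2_variables:
        allowed = list(roster.t1_variables)
        if roster.message is not None:
            allowed.append(roster.message)
        if allow_intra_t2:
            allowed += [v for v in roster.t2_variables if v != node]
        report.entries[node] = screen_parent_sets(node, allowed, data, max_parents_t2, top_k)
    candidates = enumerate_candidates(report.entries, roster)
    best = select_structure(candidates, data, alpha)
    return best, report, candidates
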