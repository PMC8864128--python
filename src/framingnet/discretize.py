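"""Quantile discretization of continuous scale scores.

The network operates on categorical variables: every scale is collapsed to
``{low, medium, high}`` by 33% quantiles, except the outcome *Delta
intention*, which uses 20% quantiles on the five-level ordered scale
``{high-negative, ..., high-positive}``.

Conventions (deterministic and platform independent):

* cut ``k`` is the smallest observed value whose empirical CDF strictly
  exceeds ``k / n_bins`` (upper inverse-CDF quantile);
* a value exactly equal to a cut belongs to the upper bin;
* duplicate cuts produced by heavy ties are merged, and cuts at or below
  the sample minimum are dropped (they can only delimit empty bottom
  bins); the realized bin count is recorded, never padded.

Out-of-range values at apply time clamp to the outer bins, which is the
natural behaviour of cut-point binning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import OUTCOME_SCALE, TERNARY_SCALE

__all__ = ["BinSpec", "DiscretizationMap", "fit_quantile_cuts", "apply_map"]

_CANONICAL_LABELS = {3: TERNARY_SCALE, 5: OUTCOME_SCALE}


@dataclass(frozen=True)
class BinSpec:
    """Fitted cut points and labels for one variable."""

    cuts: tuple[float, ...]
    labels: tuple[str, ...]
    requested_bins: int

    def __post_init__(self) -> None:
        if list(self.cuts) != sorted(set(self.cuts)):
            raise ValueError("cut points must be strictly increasing")
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError("label count must equal cut count + 1")

    @property
    def realized_bins(self) -> int:
        return len(self.cuts) + 1

    def assign(self, values) -> np.ndarray:
        """Bin labels for ``values``; values equal to a cut go upper."""
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(np.asarray(self.cuts), v, side="right")
        return np.asarray(self.labels, dtype=object)[idx]


@dataclass
class DiscretizationMap:
    """Per-variable :class:`BinSpec` collection, JSON round-trippable."""

    entries: dict[str, BinSpec]

    def to_json_dict(self) -> dict:
        return {
            var: {
                "cuts": list(spec.cuts),
                "labels": list(spec.labels),
                "requested_bins": spec.requested_bins,
            }
            for var, spec in self.entries.items()
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def from_json_dict(cls, doc: Mapping) -> "DiscretizationMap":
        return cls(
            {
                var: BinSpec(tuple(d["cuts"]), tuple(d["labels"]), int(d["requested_bins"]))
                for var, d in doc.items()
            }
        )

    @classmethod
    def load(cls, path) -> "DiscretizationMap":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


def _labels_for(realized: int, requested: int, labels: Sequence[str] | None) -> tuple[str, ...]:
    if labels is None:
        labels = _CANONICAL_LABELS.get(requested)
    if labels is None:
        labels = tuple(f"bin{i}" for i in range(requested))
    if len(labels) != requested:
        raise ValueError("label list length must equal n_bins")
    if realized == requested:
        return tuple(labels)
    if realized == 1:
        return (labels[(requested - 1) // 2],)
    # spread surviving labels evenly over the requested ordered scale
    idx = np.round(np.linspace(0, requested - 1, realized)).astype(int)
    return tuple(labels[i] for i in idx)


def fit_quantile_cuts(values, n_bins: int, labels: Sequence[str] | None = None) -> BinSpec:
    """Fit empirical quantile cut points for one variable.

    Cuts sit at the ``k / n_bins`` empirical quantiles, ``k = 1..n_bins-1``,
    using the upper inverse-CDF estimator (smallest observation whose CDF
    strictly exceeds the probability).  Heavy ties may merge cuts; the
    realized bin count is reported via the returned :class:`BinSpec`.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot fit quantile cuts on empty input")
    if np.isnan(v).any():
        raise ValueError("input contains NaN")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    s = np.sort(v)
    n = s.size
    raw = []
    for k in range(1, n_bins):
        i = int(np.ceil(k * n / n_bins))  # first index with CDF > k/n_bins
        if i >= n:
            continue
        raw.append(float(s[i]))
    lo = float(s[0])
    cuts = tuple(sorted({c for c in raw if c > lo}))
    realized = len(cuts) + 1
    if realized < n_bins:
        warnings.warn(
            f"ties reduced {n_bins} requested bins to {realized} realized bins",
            stacklevel=2,
        )
    return BinSpec(cuts, _labels_for(realized, n_bins, labels), n_bins)


def fit_map(
    table: pd.DataFrame,
    outcome: str | None = None,
    n_bins: int = 3,
    outcome_bins: int = 5,
    columns: Sequence[str] | None = None,
) -> DiscretizationMap:
    """Fit a :class:`DiscretizationMap` over the numeric columns of a table."""
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    entries = {}
    for c in cols:
        bins = outcome_bins if c == outcome else n_bins
        entries[c] = fit_quantile_cuts(table[c].to_numpy(), bins)
    return DiscretizationMap(entries)


def apply_map(table: pd.DataFrame, dmap: DiscretizationMap) -> pd.DataFrame:
    """Replace each mapped column by its bin labels.

    Non-mapped columns pass through unchanged.  Refitting on already
    discretized (non-numeric) columns is rejected upstream because
    :func:`fit_quantile_cuts` requires numeric input.
    """
    missing = [v for v in dmap.entries if v not in table.columns]
    if missing:
        raise ValueError(f"table lacks mapped variables {missing}")
    out = table.copy()
    for var, spec in dmap.entries.items():
        if not pd.api.types.is_numeric_dtype(out[var]):
            raise TypeError(f"column {var!r} is not numeric; refusing to re-discretize labels")
        out[var] = spec.assign(out[var].to_numpy())
    return out
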