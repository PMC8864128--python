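"""Synthetic two-wave message-framing cohorts.

Emulates the questionnaire data the analysis assumes: an initial pool of
participants scored on sixteen Time-1 psychosocial scales (1-7 Likert,
plus weekly red/processed-meat servings), randomized to one of four
message framings (gain, non-loss, non-gain, loss), and re-measured at
Time 2 (systematic processing, message involvement, message-induced
distress, future intention).  *Delta intention* is future minus baseline
intention.

Two generator modes:

``likert``
    Continuous scores.  Each scale is a clipped Gaussian whose *latent*
    location is calibrated so the post-clipping mean equals the configured
    scale mean (censored-normal moment matching); the structural model adds
    framing main effects, framing x moderator interactions and a mediated
    path through systematic processing on top of the baseline draws.

``categorical``
    Ancestral sampling from a supplied ground-truth categorical network,
    used to exercise structure and parameter recovery.

Eligibility mirrors the study protocol: special-diet followers, people
eating fewer than 3 weekly servings of red/processed meat, and incomplete
responders are removed, in that order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .network import FRAMINGS, CPTSet, NetworkStructure

__all__ = [
    "SCALE_DEFAULTS",
    "T1_SCALES",
    "T2_SCALES",
    "GeneratorConfig",
    "generate_cohort",
    "apply_exclusions",
    "compute_delta_intention",
]

#: Entire-sample mean and SD of every study measure (generator defaults).
SCALE_DEFAULTS: dict[str, tuple[float, float]] = {
    # Time 1
    "attitude": (4.61, 1.34),
    "subjective_norm": (3.55, 1.40),
    "perceived_behavioral_control": (4.23, 1.19),
    "baseline_intention": (4.16, 3.10),
    "past_behavior": (6.99, 3.52),  # weekly servings, >= 0
    "prevention_focus": (4.64, 0.97),
    "promotion_focus": (5.02, 0.97),
    "perceived_susceptibility": (4.02, 1.05),
    "perceived_severity": (4.16, 0.63),
    "food_involvement": (5.27, 1.14),
    "perceived_risk": (3.67, 1.19),
    "perceived_benefit": (4.08, 1.27),
    "hedonism": (4.75, 1.40),
    "diffused_responsibility": (3.68, 1.20),
    "desensitization": (3.66, 0.58),
    "denial_of_negative_consequences": (4.30, 1.19),
    # Time 2
    "systematic_processing": (4.38, 1.25),
    "message_involvement": (4.10, 1.47),
    "message_induced_distress": (1.64, 0.68),
    "future_intention": (4.38, 0.90),
}

T1_SCALES: tuple[str, ...] = tuple(list(SCALE_DEFAULTS)[:16])
T2_SCALES: tuple[str, ...] = tuple(list(SCALE_DEFAULTS)[16:])

_LIKERT_LO, _LIKERT_HI = 1.0, 7.0


def _default_interactions() -> dict[str, dict[str, float]]:
    # framing x moderator slopes on Delta intention (per centered Likert point)
    return {
        "gain": {"baseline_intention": -0.05, "prevention_focus": 0.05,
                 "perceived_severity": 0.10, "diffused_responsibility": -0.05},
        "nonloss": {"baseline_intention": -0.10, "prevention_focus": 0.10,
                    "perceived_severity": 0.05, "diffused_responsibility": -0.05},
        "nongain": {"baseline_intention": -0.05, "prevention_focus": -0.05,
                    "perceived_severity": 0.10, "diffused_responsibility": -0.10},
        "loss": {"baseline_intention": -0.15, "prevention_focus": 0.15,
                 "perceived_severity": 0.15, "diffused_responsibility": -0.10},
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Defaults reproduce the study's entire-sample descriptives, arm sizes
    and exclusion rates; structural coefficients are modest, plausible
    effects mirroring the published dependency structure (direct moderators
    of intention change: baseline intention, prevention focus, perceived
    severity, diffused responsibility; mediated through systematic
    processing: promotion focus, food involvement, perceived behavioral
    control, desensitization).
    """

    n_initial: int = 834
    seed: int | None = None
    arm_sizes: tuple[int, int, int, int] | None = None
    #: default randomization probabilities proportional to arms 134/134/136/141
    arm_probabilities: tuple[float, float, float, float] = (
        134 / 545, 134 / 545, 136 / 545, 141 / 545
    )
    scale_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SCALE_DEFAULTS)
    )
    #: optional T1 cross-scale correlation matrix (order = T1_SCALES); None = independent
    t1_correlation: np.ndarray | None = None
    #: framing main effects on future intention (Likert points)
    framing_main: dict[str, float] = field(
        default_factory=lambda: {"gain": -0.10, "nonloss": -0.15, "nongain": -0.05, "loss": -0.20}
    )
    #: framing x moderator interactions on future intention
    framing_interactions: dict[str, dict[str, float]] = field(default_factory=_default_interactions)
    #: framing effects on systematic processing (mediator)
    mediator_framing: dict[str, float] = field(
        default_factory=lambda: {"gain": -0.10, "nonloss": 0.20, "nongain": -0.15, "loss": 0.05}
    )
    #: T1 slopes on systematic processing (mediated antecedents)
    mediator_slopes: dict[str, float] = field(
        default_factory=lambda: {
            "promotion_focus": 0.20,
            "food_involvement": 0.25,
            "perceived_behavioral_control": 0.15,
            "desensitization": -0.20,
        }
    )
    #: slope of future intention on (centered) systematic processing
    mediator_effect: float = -0.15
    #: slope of future intention on centered baseline intention (carry-over)
    carryover: float = 0.60
    noise_sd: float = 0.60
    special_diet_rate: float = 124 / 834
    low_meat_rate: float = 96 / 834
    incomplete_rate: float = 70 / 834

    def __post_init__(self) -> None:
        if self.n_initial <= 0:
            raise ValueError("n_initial must be positive")
        for name in self.scale_params:
            if name not in SCALE_DEFAULTS:
                raise ValueError(f"unknown scale name {name!r}")
        for name, (_, sd) in self.scale_params.items():
            if sd <= 0:
                raise ValueError(f"sd for {name!r} must be > 0")
        if self.arm_sizes is None:
            p = np.asarray(self.arm_probabilities, dtype=float)
            if len(p) != 4 or not np.isclose(p.sum(), 1.0):
                raise ValueError("arm probabilities must be 4 values summing to 1")
        for coefs in (self.mediator_slopes, *self.framing_interactions.values()):
            for var in coefs:
                if var not in SCALE_DEFAULTS:
                    raise ValueError(f"structural coefficient references absent variable {var!r}")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.t1_correlation is not None:
            d["t1_correlation"] = np.asarray(self.t1_correlation).tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if d.get("t1_correlation") is not None:
            d["t1_correlation"] = np.asarray(d["t1_correlation"], dtype=float)
        if d.get("arm_sizes") is not None:
            d["arm_sizes"] = tuple(d["arm_sizes"])
        if "arm_probabilities" in d:
            d["arm_probabilities"] = tuple(d["arm_probabilities"])
        if "scale_params" in d:
            d["scale_params"] = {k: tuple(v) for k, v in d["scale_params"].items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        doc = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(doc)


# ---------------------------------------------------------------------------
# censored-normal calibration


def _censored_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """Mean of ``clip(N(mu, sd), lo, hi)``."""
    a = (lo - mu) / sd if np.isfinite(lo) else -np.inf
    b = (hi - mu) / sd if np.isfinite(hi) else np.inf
    phi_a = stats.norm.pdf(a) if np.isfinite(a) else 0.0
    phi_b = stats.norm.pdf(b) if np.isfinite(b) else 0.0
    cdf_a = stats.norm.cdf(a)
    cdf_b = stats.norm.cdf(b)
    out = mu * (cdf_b - cdf_a) + sd * (phi_a - phi_b)
    if np.isfinite(lo):
        out += lo * cdf_a
    if np.isfinite(hi):
        out += hi * (1.0 - cdf_b)
    return float(out)


def latent_location(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Latent Gaussian location whose clipped mean equals ``target_mean``."""
    if np.isfinite(lo) and np.isfinite(hi) and not (lo < target_mean < hi):
        raise ValueError("target mean must lie strictly inside the clipping bounds")
    span = 10 * sd + abs(target_mean) + 10
    return float(
        optimize.brentq(
            lambda m: _censored_mean(m, sd, lo, hi) - target_mean,
            target_mean - span,
            target_mean + span,
            xtol=1e-10,
        )
    )


def _clip_likert(x: np.ndarray) -> np.ndarray:
    return np.clip(x, _LIKERT_LO, _LIKERT_HI)


# ---------------------------------------------------------------------------
# generation


def generate_cohort(
    config: GeneratorConfig,
    mode: str = "likert",
    structure: NetworkStructure | None = None,
    cpts: CPTSet | None = None,
) -> pd.DataFrame:
    """Generate one randomized two-wave cohort.

    In ``likert`` mode returns one row per participant with continuous
    scale scores, eligibility flags, condition and *Delta intention*.  In
    ``categorical`` mode performs ancestral sampling over the supplied
    ground-truth network and returns categorical labels.
    """
    if config.seed is None:
        raise ValueError("config.seed is mandatory for cohort generation")
    rng = np.random.default_rng(config.seed)
    if mode == "likert":
        return _generate_likert(config, rng)
    if mode == "categorical":
        if structure is None or cpts is None:
            raise ValueError("categorical mode requires a ground-truth structure and CPTs")
        return sample_from_network(structure, cpts, config.n_initial, rng)
    raise ValueError(f"unknown mode {mode!r}")


def _assign_conditions(config: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.arm_sizes is not None:
        if sum(config.arm_sizes) != n:
            raise ValueError("arm_sizes must sum to the cohort size")
        pool = np.repeat(np.arange(4), config.arm_sizes)
        rng.shuffle(pool)
        idx = pool
    else:
        idx = rng.choice(4, size=n, p=np.asarray(config.arm_probabilities))
    return np.asarray(FRAMINGS, dtype=object)[idx]


def _generate_likert(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_initial
    params = config.scale_params

    # Time-1 scales: (optionally correlated) calibrated clipped Gaussians
    z = rng.standard_normal((n, len(T1_SCALES)))
    if config.t1_correlation is not None:
        corr = np.asarray(config.t1_correlation, dtype=float)
        if corr.shape != (len(T1_SCALES), len(T1_SCALES)):
            raise ValueError("t1_correlation must be square over the 16 T1 scales")
        z = z @ np.linalg.cholesky(corr).T
    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(T1_SCALES):
        mean, sd = params[name]
        if name == "past_behavior":
            continue  # drawn below, tied to the low-meat exclusion rate
        mu = latent_location(mean, sd, _LIKERT_LO, _LIKERT_HI)
        data[name] = _clip_likert(mu + sd * z[:, j])

    # weekly servings: mixture of truncated normals so that the < 3 servings
    # eligibility rule fires at the configured rate
    pb_mean, pb_sd = params["past_behavior"]
    low = rng.random(n) < config.low_meat_rate
    a_lo, b_lo = (0.0 - pb_mean) / pb_sd, (3.0 - pb_mean) / pb_sd
    a_hi, b_hi = (3.0 - pb_mean) / pb_sd, np.inf
    servings = np.where(
        low,
        stats.truncnorm.ppf(rng.random(n), a_lo, b_lo, loc=pb_mean, scale=pb_sd),
        stats.truncnorm.ppf(rng.random(n), a_hi, b_hi, loc=pb_mean, scale=pb_sd),
    )
    data["past_behavior"] = servings

    condition = _assign_conditions(config, n, rng)
    arm_idx = {f: i for i, f in enumerate(FRAMINGS)}

    def centered(name: str) -> np.ndarray:
        return data[name] - params[name][0]

    # mediator: systematic processing
    sp_mean, sp_sd = params["systematic_processing"]
    sp = latent_location(sp_mean, sp_sd, _LIKERT_LO, _LIKERT_HI) + sp_sd * rng.standard_normal(n)
    sp = sp + np.array([config.mediator_framing[c] for c in condition])
    for var, slope in config.mediator_slopes.items():
        sp = sp + slope * centered(var)
    data["systematic_processing"] = _clip_likert(sp)

    # other Time-2 reception scales: plain calibrated draws
    for name in ("message_involvement", "message_induced_distress"):
        mean, sd = params[name]
        mu = latent_location(mean, sd, _LIKERT_LO, _LIKERT_HI)
        data[name] = _clip_likert(mu + sd * rng.standard_normal(n))

    # outcome: future intention with framing main effects, moderation and
    # the mediated path through systematic processing
    fi_mean, fi_sd = params["future_intention"]
    resid_sd = max(np.sqrt(max(fi_sd**2 - config.noise_sd**2, 1e-6)), 1e-3)
    fi = latent_location(fi_mean, fi_sd, _LIKERT_LO, _LIKERT_HI) + resid_sd * rng.standard_normal(n)
    fi = fi + config.carryover * centered("baseline_intention")
    fi = fi + np.array([config.framing_main[c] for c in condition])
    for framing, coefs in config.framing_interactions.items():
        mask = condition == framing
        for var, slope in coefs.items():
            fi[mask] += slope * centered(var)[mask]
    fi = fi + config.mediator_effect * (
        data["systematic_processing"] - sp_mean
    )
    fi = fi + config.noise_sd * rng.standard_normal(n)
    data["future_intention"] = _clip_likert(fi)

    out = pd.DataFrame(data, columns=list(SCALE_DEFAULTS))
    out.insert(0, "id", [f"p{i:05d}" for i in range(n)])
    out["condition"] = condition
    out["special_diet_flag"] = rng.random(n) < config.special_diet_rate
    out["complete_flag"] = rng.random(n) >= config.incomplete_rate
    out["delta_intention"] = out["future_intention"] - out["baseline_intention"]
    return out


def sample_from_network(
    structure: NetworkStructure,
    cpts: CPTSet,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Ancestral sampling of ``n`` complete categorical records."""
    if n <= 0:
        raise ValueError("n must be positive")
    cols: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    for name in structure.topological_order():
        cats = structure.categories(name)
        parents = structure.parents(name)
        cfg = np.zeros(n, dtype=np.int64)
        for p in parents:
            cfg = cfg * len(structure.categories(p)) + codes[p]
        table = cpts.tables[name]
        u = rng.random(n)
        cum = np.cumsum(table, axis=1)
        codes[name] = (u[:, None] > cum[cfg]).sum(axis=1)
        cols[name] = np.asarray(cats, dtype=object)[codes[name]]
    return pd.DataFrame({name: cols[name] for name in structure.names})


# ---------------------------------------------------------------------------
# eligibility and outcome


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study eligibility filter.

    Removes, in order: special-diet followers, participants eating fewer
    than 3 weekly servings of red/processed meat, and incomplete
    responders.  A record triggering several rules is counted only under
    the first rule applied.

    Returns
    -------
    (survivors, counts)
        ``counts`` maps ``special_diet`` / ``low_meat`` / ``incomplete``
        to the number of records removed by each rule.
    """
    required = {"special_diet_flag", "past_behavior", "complete_flag"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")
    remaining = table
    counts: dict[str, int] = {}
    rules = [
        ("special_diet", remaining["special_diet_flag"].astype(bool)),
        ("low_meat", remaining["past_behavior"] < 3.0),
        ("incomplete", ~remaining["complete_flag"].astype(bool)),
    ]
    removed = pd.Series(False, index=table.index)
    for rule_name, mask in rules:
        hits = mask & ~removed
        counts[rule_name] = int(hits.sum())
        removed |= hits
    return table.loc[~removed].copy(), counts


def compute_delta_intention(baseline: float, future: float) -> float:
    """Change in intention: Time-2 minus Time-1 intention, in [-6, 6]."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(future, dtype=float)
    if ((b < 1) | (b > 7) | (f < 1) | (f > 7)).any():
        raise ValueError("intention scores must lie in [1, 7]")
    out = f - b
    return out.item() if np.isscalar(baseline) and np.isscalar(future) else out
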