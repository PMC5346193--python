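"""Covariate-adaptive minimisation with an independent algorithm per scheme.

The allocator is marginal-totals Pocock-Simon: for each candidate arm the
imbalance score is the weighted sum, over minimisation factors, of that arm's
running count at the incoming participant's factor level.  The lowest-scoring
arm is assigned with probability ``p`` (default 0.8); otherwise one of the
remaining arms is drawn uniformly.  Exact ties among minimal arms are broken
uniformly at random.

Because each randomisation scheme recruits its own sub-population, every
scheme keeps its own state table by default and allocations in one scheme
never touch another's counts; a shared-state mode (one pooled table across
schemes) is available behind a flag.

Every allocation consumes exactly two RNG draws — a uniform for the biased
coin and an integer index for the within-set choice — so a logged (seed,
draw index) pair replays any allocation sequence bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .design import Scheme, TrialDesign
from .errors import ConfigurationError, UnknownIdError, ValidationError

SHARED_KEY = "__shared__"


@dataclass
class MinimisationConfig:
    """Tunables of the minimisation algorithm.

    p : probability of assigning the imbalance-minimising arm, in (0.5, 1].
    weights : per-factor weights (default: all 1).
    tie_break : "uniform" is the only shipped rule.
    shared_state : pool counts across schemes instead of one table per scheme.
    """

    p: float = 0.8
    weights: Optional[dict[str, float]] = None
    tie_break: str = "uniform"
    shared_state: bool = False

    def __post_init__(self):
        if not 0.5 < self.p <= 1.0:
            raise ConfigurationError("assignment probability p must lie in (0.5, 1]")
        if self.tie_break != "uniform":
            raise ConfigurationError(f"unknown tie_break rule {self.tie_break!r}")
        if self.weights is not None and any(w < 0 for w in self.weights.values()):
            raise ConfigurationError("factor weights must be >= 0")

    def weight(self, factor_id: str) -> float:
        if self.weights is None:
            return 1.0
        return self.weights.get(factor_id, 1.0)


@dataclass
class AuditEntry:
    """One allocation, sufficient to replay it bit-exactly."""

    participant_id: str
    scheme_id: str
    levels: dict[str, str]
    scores: dict[str, float]
    chosen_arm: str
    draw_index: int


@dataclass
class MinimisationState:
    """Running marginal counts per scheme: count[factor][level][arm] and totals."""

    design: TrialDesign
    counts: dict[str, dict[str, dict[str, dict[str, int]]]] = field(default_factory=dict)
    totals: dict[str, dict[str, int]] = field(default_factory=dict)
    draw_index: int = 0
    audit: list[AuditEntry] = field(default_factory=list)

    def _key(self, scheme: Scheme, config: MinimisationConfig) -> str:
        return SHARED_KEY if config.shared_state else scheme.scheme_id

    def ensure(self, key: str, arm_ids: list[str]) -> None:
        if key in self.counts:
            return
        self.counts[key] = {
            f.factor_id: {lev: {a: 0 for a in arm_ids} for lev in f.levels}
            for f in self.design.factors
        }
        self.totals[key] = {a: 0 for a in arm_ids}

    def n_allocated(self, scheme_id: str) -> int:
        return sum(self.totals.get(scheme_id, {}).values())

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "totals": self.totals,
            "draw_index": self.draw_index,
        }

    @classmethod
    def from_dict(cls, design: TrialDesign, payload: Mapping) -> "MinimisationState":
        return cls(
            design=design,
            counts={k: {f: {l: dict(a) for l, a in levs.items()}
                        for f, levs in facs.items()}
                    for k, facs in payload["counts"].items()},
            totals={k: dict(v) for k, v in payload["totals"].items()},
            draw_index=int(payload.get("draw_index", 0)),
        )


def _scores(
    levels: Mapping[str, str],
    arm_ids: list[str],
    table: dict[str, dict[str, dict[str, int]]],
    config: MinimisationConfig,
) -> dict[str, float]:
    scores = {}
    for arm in arm_ids:
        s = 0.0
        for factor_id, level in levels.items():
            s += config.weight(factor_id) * table[factor_id][level][arm]
        scores[arm] = s
    return scores


def allocate(
    participant_levels: Mapping[str, str],
    scheme: Scheme,
    state: MinimisationState,
    config: MinimisationConfig,
    rng: np.random.Generator,
    participant_id: str = "",
) -> str:
    """Allocate one participant within a scheme and update the state.

    Raises ValidationError when a factor level is missing or unknown, and
    UnknownIdError when the scheme references undeclared arms; in either
    case the state is left untouched and no RNG draw is consumed.
    """
    design = state.design
    for arm in scheme.arm_ids:
        design.arm(arm)  # raises UnknownIdError
    levels: dict[str, str] = {}
    for f in design.factors:
        if f.factor_id not in participant_levels:
            raise ValidationError(f"missing level for factor {f.factor_id!r}")
        lev = participant_levels[f.factor_id]
        if lev not in f.levels:
            raise ValidationError(
                f"unknown level {lev!r} for factor {f.factor_id!r}"
            )
        levels[f.factor_id] = lev

    arm_ids = sorted(scheme.arm_ids)
    key = state._key(scheme, config)
    state.ensure(key, design.arm_ids if config.shared_state else arm_ids)
    table = state.counts[key]
    scores = _scores(levels, arm_ids, table, config)

    smin = min(scores.values())
    minimal = [a for a in arm_ids if scores[a] == smin]
    others = [a for a in arm_ids if scores[a] > smin]

    # Two draws per allocation, always consumed, for stable replay.
    coin = rng.random()
    u = rng.random()
    pool = minimal if (not others or coin < config.p) else others
    chosen = pool[min(int(u * len(pool)), len(pool) - 1)]

    for factor_id, level in levels.items():
        table[factor_id][level][chosen] += 1
    state.totals[key][chosen] += 1
    state.draw_index += 2
    state.audit.append(
        AuditEntry(
            participant_id=participant_id,
            scheme_id=scheme.scheme_id,
            levels=levels,
            scores=scores,
            chosen_arm=chosen,
            draw_index=state.draw_index,
        )
    )
    return chosen


def imbalance_report(state: MinimisationState, scheme: Scheme) -> dict[str, dict[str, int]]:
    """Per-factor, per-level max absolute pairwise difference in arm counts."""
    key = scheme.scheme_id if scheme.scheme_id in state.counts else SHARED_KEY
    report: dict[str, dict[str, int]] = {}
    for f in state.design.factors:
        report[f.factor_id] = {}
        for lev in f.levels:
            if key in state.counts:
                vals = list(state.counts[key][f.factor_id][lev].values())
                report[f.factor_id][lev] = max(vals) - min(vals) if vals else 0
            else:
                report[f.factor_id][lev] = 0
    return report
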