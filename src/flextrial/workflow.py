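"""End-to-end pilot-design workflow: cohort -> uptake -> feasibility -> adaptation.

``run_pilot_workflow`` chains the stages into one reproducible report bundle:
generate or load the pilot cohort, allocate it with per-scheme minimisation,
summarise uptake, apply the feasibility rule to every candidate, emit the
adapted design, and solve both sample-size blocks.  Every stage failure is
re-raised tagged with its stage name; the bundle records seed, a config hash
and the package version so a run is reproducible from its own report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import __version__
from .accrual import (
    CovariateModel,
    EligibilityModel,
    Participant,
    PreferenceModel,
    pilot_fixture,
    simulate_accrual,
    summarise_uptake,
)
from .design import Scheme, TrialDesign
from .errors import FlexTrialError, StageError
from .feasibility import FeasibilityRule, adapt_design, rank_candidates
from .io import design_to_dict, flow_summary_to_dict
from .minimisation import MinimisationConfig, MinimisationState, allocate


@dataclass
class RunConfig:
    """Configuration of one pilot-design run."""

    design: TrialDesign
    seed: int = 0
    mode: str = "fixture"  # "fixture" or "simulate"
    n_screened: int = 504
    comparator_arm: str = "COCP"
    allocate_cohort: bool = True
    minimisation: MinimisationConfig = field(default_factory=MinimisationConfig)
    eligibility: Optional[EligibilityModel] = None
    preference: Optional[PreferenceModel] = None
    covariates: Optional[CovariateModel] = None
    rule: Optional[FeasibilityRule] = None


def allocate_cohort(
    participants: Iterable[Participant],
    design: TrialDesign,
    config: MinimisationConfig,
    seed: int,
) -> MinimisationState:
    """Run the per-scheme minimisation over a cohort, filling allocations."""
    state = MinimisationState(design=design)
    rng = np.random.default_rng(seed)
    for p in participants:
        scheme = Scheme(p.accepted_arms)
        p.allocated_arm = allocate(
            p.levels(), scheme, state, config, rng, participant_id=p.participant_id
        )
    return state


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pilot_workflow(config: RunConfig) -> dict:
    """Execute the full pilot pipeline and return the JSON-ready bundle."""
    design = config.design
    stage = "cohort"
    try:
        if config.mode == "fixture":
            participants, flow = pilot_fixture(design, seed=config.seed)
        elif config.mode == "simulate":
            participants, flow = simulate_accrual(
                design,
                config.eligibility or EligibilityModel.pilot_empirical(),
                config.preference or PreferenceModel.pilot_empirical(design),
                config.covariates or CovariateModel(),
                config.n_screened,
                config.seed,
            )
        else:
            raise FlexTrialError(f"unknown mode {config.mode!r}")

        if config.allocate_cohort:
            stage = "allocate"
            state = allocate_cohort(
                participants, design, config.minimisation, config.seed + 1
            )
            flow.per_arm_allocated = {
                a: sum(
                    t.get(a, 0) for t in state.totals.values()
                )
                for a in design.arm_ids
            }

        stage = "summarise"
        uptake = summarise_uptake(participants, design)

        stage = "feasibility"
        rule = config.rule or design.feasibility or FeasibilityRule()
        ranked = rank_candidates(participants, design, rule)

        stage = "adapt"
        adapted = adapt_design(
            participants, design, comparator_arm=config.comparator_arm, rule=rule
        )

        stage = "samplesize"
        original_ss = design.samplesize.solve() if design.samplesize else None
        revised_ss = adapted.samplesize.solve()
    except FlexTrialError as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc

    cfg_payload = {
        "design": design_to_dict(design),
        "seed": config.seed,
        "mode": config.mode,
        "n_screened": config.n_screened,
        "comparator_arm": config.comparator_arm,
        "minimisation": asdict(config.minimisation),
    }
    return {
        "meta": {
            "package": "flextrial",
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(cfg_payload),
        },
        "flow": flow_summary_to_dict(flow),
        "uptake": asdict(uptake),
        "feasibility": {
            "rule": {"threshold": rule.threshold, "metric": rule.metric},
            "candidates": [
                {
                    "scheme_id": c.scheme_id,
                    "feasible": c.feasible,
                    "metrics": c.metrics,
                }
                for c in ranked
            ],
        },
        "adapted_design": asdict(adapted),
        "samplesize": {"original": original_ss, "revised": revised_ss},
    }
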