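"""Internal-pilot feasibility rule, candidate ranking and design adaptation.

The prespecified rule: a candidate design is infeasible when it attracts
less than a threshold fraction (default 10%) of the randomisations.  The
phrase admits two readings, both implemented and always reported:

* ``compatible_uptake`` — the fraction of pilot participants whose accepted
  arm set contains every arm of the candidate (they *could* enter it); this
  is how designs were actually ruled in or out.
* ``allocation_share`` — the literal per-arm reading: the smallest share of
  realised allocations any candidate arm received (requires allocations).

A third supporting figure, ``scheme_selection`` (participants whose accepted
set equals the candidate exactly), is reported because sole-design options
were also discussed in terms of how many participants picked precisely that
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .accrual import Participant
from .design import TrialDesign, enumerate_schemes, scheme_id_for, validate_scheme
from .errors import ConfigurationError, ValidationError
from .samplesize import SampleSizeSpec


@dataclass
class FeasibilityRule:
    """Threshold rule applied to pilot uptake."""

    threshold: float = 0.10
    metric: str = "compatible_uptake"

    def __post_init__(self):
        if not 0 <= self.threshold < 1:
            raise ConfigurationError("threshold must lie in [0, 1)")
        if self.metric not in ("compatible_uptake", "allocation_share"):
            raise ConfigurationError(f"unknown feasibility metric {self.metric!r}")


@dataclass
class CandidateDesign:
    """A candidate arm subset with its evaluated feasibility verdict."""

    arm_ids: frozenset[str]
    feasible: Optional[bool] = None
    metrics: dict = field(default_factory=dict)

    @property
    def scheme_id(self) -> str:
        return scheme_id_for(self.arm_ids)


@dataclass
class AdaptedDesign:
    """The post-pilot design emitted by the adaptation rule.

    Either the original multi-arm design (when it passed the rule) or a
    class-versus-comparator two-group design in which the class member is
    chosen by the participant before randomisation (strata: each class
    member plus "no-preference", the latter sub-randomised among members).
    """

    kind: str  # "unchanged" or "class_vs_comparator"
    comparison: tuple[str, str]  # (class or arm, comparator arm)
    strata: tuple[str, ...]
    sub_randomisation: Optional[tuple[str, ...]]
    samplesize: SampleSizeSpec
    arms: tuple[str, ...]


def evaluate_candidate(
    candidate_arms: Iterable[str],
    participants: Iterable[Participant],
    rule: FeasibilityRule,
    design: Optional[TrialDesign] = None,
) -> CandidateDesign:
    """Score one candidate arm subset against the pilot cohort.

    ``compatible_uptake`` and ``scheme_selection`` are always computed;
    ``allocation_share`` only when every participant carries an allocation.
    The verdict compares the configured metric against the threshold.
    """
    candidate = frozenset(candidate_arms)
    participants = list(participants)
    if not participants:
        raise ValidationError("no randomised participants to evaluate")
    if design is not None:
        validate_scheme(design, candidate)
    n = len(participants)

    compatible = sum(1 for p in participants if candidate <= p.accepted_arms)
    exact = sum(1 for p in participants if p.accepted_arms == candidate)
    metrics = {
        "compatible_uptake": compatible / n,
        "compatible_count": compatible,
        "scheme_selection": exact / n,
        "scheme_selection_count": exact,
        "n": n,
    }
    allocated = [p.allocated_arm for p in participants if p.allocated_arm is not None]
    if allocated:
        shares = {a: allocated.count(a) / n for a in candidate}
        metrics["allocation_share"] = min(shares.values())
        metrics["allocation_share_per_arm"] = shares
    if rule.metric == "allocation_share" and "allocation_share" not in metrics:
        raise ValidationError("allocation_share metric requires allocated participants")

    value = metrics[rule.metric]
    return CandidateDesign(
        arm_ids=candidate, feasible=value >= rule.threshold, metrics=metrics
    )


def rank_candidates(
    participants: Iterable[Participant],
    design: TrialDesign,
    rule: FeasibilityRule,
) -> list[CandidateDesign]:
    """Evaluate every admissible candidate (all schemes) and rank them.

    Sorted by the configured metric descending; ties broken by arm count
    descending (prefer retaining more arms) then scheme_id.
    """
    participants = list(participants)
    out = [
        evaluate_candidate(s.arm_ids, participants, rule, design)
        for s in enumerate_schemes(design)
    ]
    out.sort(key=lambda c: (-c.metrics[rule.metric], -len(c.arm_ids), c.scheme_id))
    return out


# Revised numeric block attached to the adapted two-group design: 8-point
# difference, SD 22, 90% power, two-sided 0.05, 20% attrition.
REVISED_SAMPLESIZE = dict(
    delta=8.0, sd=22.0, alpha=0.05, power=0.90, n_groups=2, attrition=0.20, round_to=1
)


def adapt_design(
    participants: Iterable[Participant],
    design: TrialDesign,
    comparator_arm: str,
    preference_class: Optional[str] = None,
    rule: Optional[FeasibilityRule] = None,
    revised_samplesize: Optional[SampleSizeSpec] = None,
) -> AdaptedDesign:
    """Apply the pilot decision rule and emit the substantive-phase design.

    When the full multi-arm design passes the rule it is retained unchanged
    (original sample-size block).  Otherwise the fallback is the
    class-versus-comparator design: participants choose their preferred
    member of ``preference_class`` before randomisation (or enter a
    no-preference stratum with sub-randomisation among the members), and the
    main comparison is that class as a whole against ``comparator_arm``.
    The comparator is an input, not an inference: in the reference trial it
    was chosen on external-evidence grounds.
    """
    participants = list(participants)
    rule = rule or design.feasibility or FeasibilityRule()
    design.arm(comparator_arm)
    if preference_class is None:
        others = [c for c in design.classes if c != design.class_of(comparator_arm)]
        if len(others) != 1:
            raise ConfigurationError(
                "preference_class must be given for designs with > 2 classes"
            )
        preference_class = others[0]
    if preference_class not in design.classes:
        raise ConfigurationError(f"unknown class {preference_class!r}")

    full = evaluate_candidate(design.arm_ids, participants, rule, design)
    if full.feasible:
        ss = design.samplesize or SampleSizeSpec(**REVISED_SAMPLESIZE)
        return AdaptedDesign(
            kind="unchanged",
            comparison=(preference_class, comparator_arm),
            strata=(),
            sub_randomisation=None,
            samplesize=ss,
            arms=tuple(design.arm_ids),
        )

    members = tuple(sorted(design.arms_in_class(preference_class)))
    if not members:
        raise ConfigurationError("pilot inconclusive: no adaptation rule configured")
    ss = revised_samplesize or SampleSizeSpec(**REVISED_SAMPLESIZE)
    return AdaptedDesign(
        kind="class_vs_comparator",
        comparison=(preference_class, comparator_arm),
        strata=members + ("no-preference",),
        sub_randomisation=members,
        samplesize=ss,
        arms=members + (comparator_arm,),
    )


def stratified_analysis_sets(
    participants: Iterable[Participant],
    adapted: AdaptedDesign,
    prerandomisation_choice: dict[str, str],
) -> dict[str, list[str]]:
    """Membership of each stratified comparison in the adapted design.

    ``prerandomisation_choice`` maps participant_id to the class member
    chosen before randomisation (or "no-preference").  Only participants who
    preselected a member enter that member's versus-comparator comparison —
    choosing after seeing the allocation would bias the stratified analyses.
    """
    sets: dict[str, list[str]] = {s: [] for s in adapted.strata}
    for p in participants:
        choice = prerandomisation_choice.get(p.participant_id)
        if choice in sets:
            sets[choice].append(p.participant_id)
    return sets
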