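"""Trial-design domain model and the algebra of admissible randomisation schemes.

A flexible-entry design partitions its treatment arms into classes (in the
reference configuration: long-acting reversible contraceptives, LARC, versus
non-LARC comparators).  A *scheme* is a subset of arms a participant agrees to
be randomised among; it is admissible when it contains at least one arm from
every class, so every realised randomisation still compares the classes of
interest.  With ``a`` arms in one class and ``b`` in the other there are
``(2**a - 1) * (2**b - 1)`` admissible schemes — nine for the 2x2 reference
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations, product
from typing import TYPE_CHECKING, Iterable, Optional

from .errors import ConfigurationError, SchemeConstraintError, UnknownIdError

if TYPE_CHECKING:  # pragma: no cover
    from .feasibility import FeasibilityRule
    from .samplesize import SampleSizeSpec

SCHEME_SEP = "+"


@dataclass(frozen=True)
class Arm:
    """A treatment arm belonging to a declared treatment class."""

    arm_id: str
    class_id: str
    label: str = ""

    def __post_init__(self):
        if not self.arm_id:
            raise ConfigurationError("arm_id must be a non-empty token")
        if SCHEME_SEP in self.arm_id:
            raise ConfigurationError(
                f"arm_id {self.arm_id!r} may not contain {SCHEME_SEP!r} "
                "(reserved as the scheme-id separator)"
            )


@dataclass(frozen=True)
class Factor:
    """A minimisation/stratification factor with >= 2 ordered levels."""

    factor_id: str
    levels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise ConfigurationError(f"factor {self.factor_id!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError(f"factor {self.factor_id!r} has duplicate levels")


def scheme_id_for(arm_ids: Iterable[str]) -> str:
    """Canonical scheme token: sorted arm ids joined by ``+``."""
    return SCHEME_SEP.join(sorted(arm_ids))


@dataclass(frozen=True)
class Scheme:
    """An admissible subset of arms a participant accepts randomisation among."""

    arm_ids: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "arm_ids", frozenset(self.arm_ids))

    @property
    def scheme_id(self) -> str:
        return scheme_id_for(self.arm_ids)

    def __len__(self) -> int:
        return len(self.arm_ids)

    def covers(self, candidate_arms: Iterable[str]) -> bool:
        """True iff every arm of ``candidate_arms`` was accepted."""
        return set(candidate_arms) <= self.arm_ids


@dataclass
class TrialDesign:
    """Arms grouped into classes, plus factors and the design's numeric blocks.

    Parameters
    ----------
    arms
        Treatment arms; every ``class_id`` must appear in ``classes``.
    classes
        Declared treatment-class tokens (two in the reference design; any
        number >= 2 is supported, each contributing >= 1 arm).
    factors
        Minimisation factors.
    feasibility, samplesize
        Optional numeric blocks used by the pilot decision rule and the
        sample-size machinery.
    """

    arms: list[Arm]
    classes: list[str]
    factors: list[Factor] = field(default_factory=list)
    feasibility: Optional["FeasibilityRule"] = None
    samplesize: Optional["SampleSizeSpec"] = None

    def __post_init__(self):
        ids = [a.arm_id for a in self.arms]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("arm_id values must be unique")
        if len(self.arms) < 2:
            raise ConfigurationError("a design needs >= 2 arms")
        if len(self.classes) != len(set(self.classes)):
            raise ConfigurationError("class tokens must be unique")
        for a in self.arms:
            if a.class_id not in self.classes:
                raise ConfigurationError(
                    f"arm {a.arm_id!r} names undeclared class {a.class_id!r}"
                )
        for c in self.classes:
            if not self.arms_in_class(c):
                raise ConfigurationError(f"class {c!r} has no arms")
        fids = [f.factor_id for f in self.factors]
        if len(fids) != len(set(fids)):
            raise ConfigurationError("factor_id values must be unique")

    # -- lookups -----------------------------------------------------------
    @property
    def arm_ids(self) -> list[str]:
        return [a.arm_id for a in self.arms]

    def arm(self, arm_id: str) -> Arm:
        for a in self.arms:
            if a.arm_id == arm_id:
                return a
        raise UnknownIdError(f"unknown arm id {arm_id!r}")

    def arms_in_class(self, class_id: str) -> list[str]:
        return [a.arm_id for a in self.arms if a.class_id == class_id]

    def class_of(self, arm_id: str) -> str:
        return self.arm(arm_id).class_id

    def factor(self, factor_id: str) -> Factor:
        for f in self.factors:
            if f.factor_id == factor_id:
                return f
        raise UnknownIdError(f"unknown factor id {factor_id!r}")


def validate_scheme(design: TrialDesign, arm_ids: Iterable[str]) -> Scheme:
    """Check an arm subset against the design and return its canonical Scheme.

    Raises
    ------
    UnknownIdError
        If an arm id is not declared in the design.
    SchemeConstraintError
        If the subset misses a treatment class or has fewer than two arms.
    """
    arm_ids = set(arm_ids)
    known = set(design.arm_ids)
    unknown = arm_ids - known
    if unknown:
        raise UnknownIdError(f"unknown arm id(s): {sorted(unknown)}")
    for c in design.classes:
        if not arm_ids & set(design.arms_in_class(c)):
            raise SchemeConstraintError(
                f"scheme violates class constraint: no arm from class {c!r}"
            )
    if len(arm_ids) < 2:
        raise SchemeConstraintError("a scheme needs >= 2 arms")
    return Scheme(frozenset(arm_ids))


def enumerate_schemes(design: TrialDesign) -> list[Scheme]:
    """Every admissible scheme of the design, in canonical (scheme_id) order.

    The count equals the product over classes of ``2**n_arms - 1``.
    """
    per_class: list[list[tuple[str, ...]]] = []
    for c in design.classes:
        members = design.arms_in_class(c)
        subsets = list(
            chain.from_iterable(
                combinations(members, k) for k in range(1, len(members) + 1)
            )
        )
        per_class.append(subsets)
    schemes = [
        Scheme(frozenset(chain.from_iterable(pick))) for pick in product(*per_class)
    ]
    return sorted(schemes, key=lambda s: s.scheme_id)


def scheme_compatible_with_design(scheme: Scheme, candidate_arms: Iterable[str]) -> bool:
    """True iff the participant's scheme accepts every arm of a candidate design."""
    return scheme.covers(candidate_arms)
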