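"""The shipped reference configuration: the 2x2 endometriosis-recurrence trial.

Two long-acting reversible contraceptives (LNG-IUS, a five-year uterine
insert; DMPA, a three-monthly injection) form the LARC class; the combined
oral contraceptive pill and no treatment form the comparator class.  Four
minimisation factors: disease stage (I-IV), extent of surgical excision,
age group and recruiting centre (six centres).
"""

from __future__ import annotations

from .design import Arm, Factor, TrialDesign
from .feasibility import FeasibilityRule
from .samplesize import SampleSizeSpec

CENTRES = ("C1", "C2", "C3", "C4", "C5", "C6")

# Original four-arm sample-size block: 10-point difference on the 0-100
# pain score, SD 25, alpha 0.01 (0.05 Bonferroni-adjusted for the 6
# pairwise comparisons, rounded to 2 dp), 80% power, 20% attrition with
# recruitment rounded up to a multiple of 50.
FOUR_ARM_SAMPLESIZE = SampleSizeSpec(
    delta=10.0, sd=25.0, alpha=0.01, power=0.80, n_groups=4,
    attrition=0.20, round_to=50,
)


def reference_design(centres: tuple[str, ...] = CENTRES) -> TrialDesign:
    """The four-arm, two-class flexible-entry reference design."""
    return TrialDesign(
        arms=[
            Arm("LNG-IUS", "LARC", "levonorgestrel intrauterine system"),
            Arm("DMPA", "LARC", "depot medroxyprogesterone acetate"),
            Arm("COCP", "non-LARC", "combined oral contraceptive pill"),
            Arm("NONE", "non-LARC", "no treatment"),
        ],
        classes=["LARC", "non-LARC"],
        factors=[
            Factor("stage", ("I", "II", "III", "IV")),
            Factor("excision", ("complete", "incomplete")),
            Factor("age_group", ("<35", ">=35")),
            Factor("centre", tuple(centres)),
        ],
        feasibility=FeasibilityRule(threshold=0.10, metric="compatible_uptake"),
        samplesize=FOUR_ARM_SAMPLESIZE,
    )
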