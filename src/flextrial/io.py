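"""File formats: design YAML/JSON, participants CSV, summaries as JSON.

Participants travel as delimited text with the documented header::

    participant_id,centre,age,age_group,stage,excision,bmi,smoking,
    ehp30_pain,accepted_arms,scheme_id,allocated_arm

``accepted_arms`` is the '+'-joined canonical arm list; empty fields are
missing values.  ``age_group`` and ``scheme_id`` are derived columns written
for human readers and checked (not trusted) on read.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

from .accrual import Participant, TrialFlowSummary
from .design import Arm, Factor, TrialDesign, validate_scheme
from .errors import ConfigurationError, FlexTrialError, ValidationError
from .feasibility import FeasibilityRule
from .samplesize import SampleSizeSpec

PARTICIPANT_COLUMNS = [
    "participant_id", "centre", "age", "age_group", "stage", "excision",
    "bmi", "smoking", "ehp30_pain", "accepted_arms", "scheme_id",
    "allocated_arm",
]
REQUIRED_COLUMNS = [
    "participant_id", "centre", "age", "stage", "excision", "accepted_arms",
]


# -- design configs ---------------------------------------------------------


def load_design(path: Union[str, Path]) -> TrialDesign:
    """Read a design config (YAML; JSON is a YAML subset and also accepted)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return design_from_dict(payload)


def design_from_dict(payload: dict) -> TrialDesign:
    try:
        arms = [
            Arm(a["arm_id"], a["class_id"], a.get("label", ""))
            for a in payload["arms"]
        ]
        factors = [
            Factor(f["factor_id"], tuple(f["levels"]))
            for f in payload.get("factors", [])
        ]
        feas = (
            FeasibilityRule(**payload["feasibility"])
            if "feasibility" in payload else None
        )
        ss = (
            SampleSizeSpec(**payload["samplesize"])
            if "samplesize" in payload else None
        )
        return TrialDesign(
            arms=arms, classes=list(payload["classes"]), factors=factors,
            feasibility=feas, samplesize=ss,
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed design config: {exc}") from exc


def design_to_dict(design: TrialDesign) -> dict:
    out: dict = {
        "arms": [
            {"arm_id": a.arm_id, "class_id": a.class_id, "label": a.label}
            for a in design.arms
        ],
        "classes": list(design.classes),
        "factors": [
            {"factor_id": f.factor_id, "levels": list(f.levels)}
            for f in design.factors
        ],
    }
    if design.feasibility is not None:
        out["feasibility"] = {
            "threshold": design.feasibility.threshold,
            "metric": design.feasibility.metric,
        }
    if design.samplesize is not None:
        out["samplesize"] = asdict(design.samplesize)
    return out


def save_design(design: TrialDesign, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


# -- participants -----------------------------------------------------------


def participants_to_frame(participants: Iterable[Participant]) -> pd.DataFrame:
    rows = []
    for p in participants:
        rows.append(
            {
                "participant_id": p.participant_id,
                "centre": p.centre,
                "age": p.age,
                "age_group": p.age_group,
                "stage": p.stage,
                "excision": p.excision,
                "bmi": p.bmi,
                "smoking": p.smoking,
                "ehp30_pain": p.ehp30_pain,
                "accepted_arms": "+".join(sorted(p.accepted_arms)),
                "scheme_id": p.scheme_id,
                "allocated_arm": p.allocated_arm,
            }
        )
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


def write_participants(
    participants: Iterable[Participant], path: Union[str, Path]
) -> None:
    # %.17g round-trips IEEE doubles exactly
    participants_to_frame(participants).to_csv(path, index=False, float_format="%.17g")


def read_participants(
    path: Union[str, Path], design: Optional[TrialDesign] = None
) -> list[Participant]:
    """Load and validate a participants CSV; malformed rows cite line numbers.

    With a design given, every accepted-arm set is checked against the class
    constraint and every allocation against the accepted set.
    """
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")
    out: list[Participant] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            accepted = frozenset(str(row["accepted_arms"]).split("+"))
            if design is not None:
                validate_scheme(design, accepted)
            p = Participant(
                participant_id=str(row["participant_id"]),
                centre=str(row["centre"]),
                age=float(row["age"]),
                stage=str(row["stage"]),
                excision=str(row["excision"]),
                bmi=None if pd.isna(row.get("bmi")) else float(row["bmi"]),
                smoking=None if pd.isna(row.get("smoking")) else str(row["smoking"]),
                ehp30_pain=(
                    None if pd.isna(row.get("ehp30_pain"))
                    else float(row["ehp30_pain"])
                ),
                accepted_arms=accepted,
                allocated_arm=(
                    None if pd.isna(row.get("allocated_arm"))
                    else str(row["allocated_arm"])
                ),
            )
            out.append(p)
        except (ValueError, TypeError, FlexTrialError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(
            "participant file failed validation:\n  " + "\n  ".join(errors)
        )
    return out


# -- summaries --------------------------------------------------------------


def flow_summary_to_dict(summary: TrialFlowSummary) -> dict:
    return asdict(summary)


def write_json(payload: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
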