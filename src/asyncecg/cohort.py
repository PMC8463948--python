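"""Cohort labeling and exclusion rules for emergency-room ECGs.

ECGs recorded within 24 h of an emergency-room visit by a patient aged 20
or older are kept.  A visit is AMI-positive when any of its ICD-10 codes
starts with I21 (acute myocardial infarction) or I22 (subsequent
infarction); subcodes such as I21.4 count via prefix matching on the
dot-stripped code.  Positive-visit ECGs are excluded — never relabeled —
when every AMI code's registration time is null or falls outside 24 h of
that ECG, since the diagnosis cannot then be tied to the recording.
Negative visits are never subject to the registration-time exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

import pandas as pd

AMI_CODE_PREFIXES = ("I21", "I22")
ECG_WINDOW_HOURS = 24.0
MIN_AGE_YEARS = 20.0


@dataclass
class VisitRecord:
    """One emergency-room visit with its diagnoses and ECG timestamps."""

    subject_id: str
    visit_time: datetime
    age: float
    diagnoses: list[tuple[str, Optional[datetime]]] = field(default_factory=list)
    ecg_times: list[datetime] = field(default_factory=list)


@dataclass
class LabeledEcg:
    subject_id: str
    visit_time: datetime
    ecg_time: datetime
    label: int


@dataclass
class Exclusion:
    subject_id: str
    ecg_time: Optional[datetime]
    reason: str


def is_ami_code(code: str) -> bool:
    """Prefix match on the normalized (dot-stripped, upper-case) code."""
    norm = code.replace(".", "").strip().upper()
    return norm.startswith(AMI_CODE_PREFIXES)


def _hours(a: datetime, b: datetime) -> float:
    return abs((a - b).total_seconds()) / 3600.0


def label_and_filter(
    visits: list[VisitRecord],
) -> tuple[list[LabeledEcg], list[Exclusion]]:
    """Apply the labeling and exclusion rules to a visit table.

    Returns the retained labeled ECGs and an exclusion log; every input
    ECG appears in exactly one of the two (conservation).  Malformed
    entries become per-record exclusion entries, not a global failure.
    The 24 h windows are closed: an ECG at exactly 24 h is retained.
    """
    kept: list[LabeledEcg] = []
    excluded: list[Exclusion] = []
    for visit in visits:
        try:
            ami_codes = [
                (code, reg) for code, reg in visit.diagnoses if is_ami_code(code)
            ]
        except AttributeError:
            for ecg_time in visit.ecg_times:
                excluded.append(
                    Exclusion(visit.subject_id, ecg_time, "malformed_diagnoses")
                )
            continue
        for ecg_time in visit.ecg_times:
            try:
                if visit.age < MIN_AGE_YEARS:
                    excluded.append(
                        Exclusion(visit.subject_id, ecg_time, "age_under_20")
                    )
                    continue
                if _hours(ecg_time, visit.visit_time) > ECG_WINDOW_HOURS:
                    excluded.append(
                        Exclusion(
                            visit.subject_id, ecg_time, "ecg_beyond_24h_of_visit"
                        )
                    )
                    continue
                if not ami_codes:
                    kept.append(
                        LabeledEcg(
                            visit.subject_id, visit.visit_time, ecg_time, 0
                        )
                    )
                    continue
                regs = [reg for _, reg in ami_codes]
                if all(reg is None for reg in regs):
                    excluded.append(
                        Exclusion(
                            visit.subject_id,
                            ecg_time,
                            "ami_code_registration_null",
                        )
                    )
                elif not any(
                    reg is not None
                    and _hours(reg, ecg_time) <= ECG_WINDOW_HOURS
                    for reg in regs
                ):
                    excluded.append(
                        Exclusion(
                            visit.subject_id,
                            ecg_time,
                            "ami_code_registration_beyond_24h",
                        )
                    )
                else:
                    kept.append(
                        LabeledEcg(
                            visit.subject_id, visit.visit_time, ecg_time, 1
                        )
                    )
            except (TypeError, ValueError) as err:
                excluded.append(
                    Exclusion(
                        visit.subject_id, None, f"malformed_timestamp: {err}"
                    )
                )
    return kept, excluded


def prevalence(labels) -> float:
    """Fraction of positives among labeled ECGs (or raw 0/1 labels)."""
    vals = [
        e.label if isinstance(e, LabeledEcg) else int(e) for e in labels
    ]
    if not vals:
        raise ValueError("prevalence of an empty collection is undefined")
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# CSV interchange

VISIT_COLUMNS = [
    "subject_id", "visit_time", "age", "icd10_codes",
    "registration_times", "ecg_times",
]


def visits_to_frame(visits: list[VisitRecord]) -> pd.DataFrame:
    """Serialize visits to the documented CSV layout (';'-joined lists)."""
    rows = []
    for v in visits:
        rows.append(
            {
                "subject_id": v.subject_id,
                "visit_time": v.visit_time.isoformat(),
                "age": v.age,
                "icd10_codes": ";".join(c for c, _ in v.diagnoses),
                "registration_times": ";".join(
                    r.isoformat() if r is not None else "null"
                    for _, r in v.diagnoses
                ),
                "ecg_times": ";".join(t.isoformat() for t in v.ecg_times),
            }
        )
    return pd.DataFrame(rows, columns=VISIT_COLUMNS)


def frame_to_visits(df: pd.DataFrame) -> list[VisitRecord]:
    visits = []
    for _, row in df.iterrows():
        codes = str(row["icd10_codes"]).split(";") if row["icd10_codes"] else []
        regs = str(row["registration_times"]).split(";") if row[
            "registration_times"
        ] else []
        diagnoses = [
            (
                c,
                None if r == "null" else datetime.fromisoformat(r),
            )
            for c, r in zip(codes, regs)
        ]
        ecg_times = [
            datetime.fromisoformat(t)
            for t in str(row["ecg_times"]).split(";")
            if t
        ]
        visits.append(
            VisitRecord(
                subject_id=str(row["subject_id"]),
                visit_time=datetime.fromisoformat(row["visit_time"]),
                age=float(row["age"]),
                diagnoses=diagnoses,
                ecg_times=ecg_times,
            )
        )
    return visits


def exclusions_to_frame(exclusions: list[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "ecg_time": e.ecg_time.isoformat() if e.ecg_time else "",
                "reason": e.reason,
            }
            for e in exclusions
        ],
        columns=["subject_id", "ecg_time", "reason"],
    )
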