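"""Lead algebra for standard 12-lead ECG reports acquired slot-wise.

A standard report prints 10 s of recording as four consecutive 2.5 s slots,
each slot holding three simultaneously recorded leads:

    slot 0 (0.0 s):  I, II, III
    slot 1 (2.5 s):  aVR, aVL, aVF
    slot 2 (5.0 s):  V1, V2, V3
    slot 3 (7.5 s):  V4, V5, V6

Leads from different slots are therefore *asynchronous* — the situation a
smartwatch user reproduces by moving the watch between body positions.  The
six limb leads are linearly dependent: Einthoven's law (II = I + III) and the
Goldberger definitions of the augmented leads

    aVR = -(I + II)/2,   aVL = I - II/2,   aVF = II - I/2

mean any two limb leads determine all six.  This module implements that
algebra, the enumeration of completely asynchronous lead subsets, and the
slicing of a report-style record into per-lead 2.5 s segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

#: Canonical lead order used everywhere (mask indices, flatten order).
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

LIMB_LEADS: tuple[str, ...] = ("I", "II", "III", "aVR", "aVL", "aVF")
PRECORDIAL_LEADS: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V5", "V6")

#: Report slots: four groups of three simultaneously recorded leads.
SLOT_GROUPS: tuple[tuple[str, ...], ...] = (
    ("I", "II", "III"),
    ("aVR", "aVL", "aVF"),
    ("V1", "V2", "V3"),
    ("V4", "V5", "V6"),
)

SLOT_DURATION = 2.5  # seconds per slot
TOTAL_DURATION = 10.0

#: lead name -> slot index (0..3)
SLOT_OF: dict[str, int] = {
    lead: i for i, group in enumerate(SLOT_GROUPS) for lead in group
}

#: Coefficients of each limb lead in the (I, II) basis.
_LIMB_COEFFS: dict[str, tuple[float, float]] = {
    "I": (1.0, 0.0),
    "II": (0.0, 1.0),
    "III": (-1.0, 1.0),
    "aVR": (-0.5, -0.5),
    "aVL": (1.0, -0.5),
    "aVF": (-0.5, 1.0),
}


class LeadAlgebraError(ValueError):
    """Base class for lead-algebra validation failures."""


class WrongLeadCountError(LeadAlgebraError):
    """Reconstruction needs exactly two known limb leads."""


class NotALimbLeadError(LeadAlgebraError):
    """A supplied lead is not one of the six limb leads."""


class LengthMismatchError(LeadAlgebraError):
    """Supplied sample arrays differ in length."""


class MissingLeadError(LeadAlgebraError):
    """A requested lead is absent and cannot be reconstructed."""


@dataclass(frozen=True)
class SlotLayout:
    """The 4-slot temporal layout of a standard 12-lead report."""

    slots: tuple[tuple[str, ...], ...] = SLOT_GROUPS
    slot_duration: float = SLOT_DURATION
    total_duration: float = TOTAL_DURATION

    def offset_of(self, lead: str) -> float:
        return SLOT_OF[lead] * self.slot_duration


DEFAULT_LAYOUT = SlotLayout()


def default_lead_offsets() -> dict[str, float]:
    """Slot-start offsets (s) for all 12 leads in the standard report."""
    return {lead: DEFAULT_LAYOUT.offset_of(lead) for lead in LEAD_NAMES}


@dataclass
class EcgRecord:
    """One 12-lead ECG report.

    ``signals`` maps lead names to sample arrays in millivolts.  All present
    arrays must share a length; ``lead_offsets`` gives each lead's
    acquisition offset in seconds (slot structure 0/2.5/5/7.5 s).
    """

    signals: dict[str, np.ndarray]
    sampling_rate: float
    lead_offsets: dict[str, float] = field(default_factory=default_lead_offsets)
    label: int = 0
    interpretation_text: Optional[str] = None
    subject_id: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise LeadAlgebraError("sampling_rate must be positive")
        if self.label not in (0, 1):
            raise LeadAlgebraError(f"label must be 0 or 1, got {self.label}")
        lengths = {lead: len(sig) for lead, sig in self.signals.items()}
        if len(set(lengths.values())) > 1:
            raise LengthMismatchError(f"signal lengths differ: {lengths}")
        for lead in self.signals:
            if lead not in LEAD_NAMES:
                raise LeadAlgebraError(f"unknown lead name {lead!r}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))


@dataclass(frozen=True)
class LeadSet:
    """An ordered subset of lead names with asynchrony metadata.

    For 2-, 3- and 4-lead sets every member originates from a distinct
    report slot (complete asynchrony); lead II in such sets is the slot-1
    version derived from the augmented leads, noted in ``derivation_note``.
    """

    leads: tuple[str, ...]
    derivation_note: str = ""

    def __post_init__(self) -> None:
        if len(set(self.leads)) != len(self.leads):
            raise LeadAlgebraError(f"duplicate leads in {self.leads}")
        for lead in self.leads:
            if lead not in LEAD_NAMES:
                raise LeadAlgebraError(f"unknown lead name {lead!r}")

    @property
    def n_leads(self) -> int:
        return len(self.leads)

    @property
    def is_asynchronous_subset(self) -> bool:
        """True for the 2-/3-/4-lead completely asynchronous sets."""
        return 2 <= self.n_leads <= 4

    def __str__(self) -> str:
        return "+".join(self.leads)


def reconstruct_limb_leads(
    known: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Recover all six limb leads from exactly two of them.

    Uses Einthoven's law and the Goldberger relations, which make the six
    limb leads a rank-2 linear system: any two determine the rest exactly.
    Supplied leads are returned unchanged (same objects are not shared; the
    returned arrays for supplied leads equal the inputs).
    """
    if len(known) != 2:
        raise WrongLeadCountError(
            f"exactly 2 limb leads required, got {len(known)}"
        )
    (la, sa), (lb, sb) = known.items()
    for lead in (la, lb):
        if lead not in LIMB_LEADS:
            raise NotALimbLeadError(f"{lead!r} is not a limb lead")
    sa = np.asarray(sa, dtype=float)
    sb = np.asarray(sb, dtype=float)
    if sa.shape != sb.shape:
        raise LengthMismatchError(
            f"lead arrays differ in shape: {sa.shape} vs {sb.shape}"
        )
    # Solve M @ [I, II] = [sa, sb] for the basis leads, sample-wise.
    m = np.array([_LIMB_COEFFS[la], _LIMB_COEFFS[lb]])
    lead_i, lead_ii = np.linalg.solve(m, np.stack([sa, sb]))
    out = {}
    for lead, (ci, cii) in _LIMB_COEFFS.items():
        out[lead] = ci * lead_i + cii * lead_ii
    # Return the supplied arrays verbatim to avoid round-off on known leads.
    out[la] = sa
    out[lb] = sb
    return out


def derived_lead_ii(avr: np.ndarray, avf: np.ndarray) -> np.ndarray:
    """Lead II computed from the slot-1 augmented leads: II = 2(aVF - aVR)/3."""
    return (2.0 / 3.0) * (np.asarray(avf, float) - np.asarray(avr, float))


_DERIVED_II_NOTE = "II derived from aVR/aVL/aVF (slot 1, offset 2.5 s)"


def enumerate_lead_sets(n_leads: int) -> list[LeadSet]:
    """Enumerate the tested lead sets for a given lead count.

    Constraints: lead I is included in every multi-lead set (it is the lead
    a smartwatch measures without being moved); 2-/3-/4-lead sets are
    completely asynchronous (one lead per slot), which forces the limb
    contribution to be lead I plus, at most, lead II derived from the
    slot-1 augmented leads; precordial members come from slots 2 and 3.
    """
    if n_leads == 1:
        return [LeadSet(("I",)), LeadSet(("II",))]
    if n_leads == 2:
        sets = [LeadSet(("I", "II"), _DERIVED_II_NOTE)]
        sets += [LeadSet(("I", v)) for v in PRECORDIAL_LEADS]
        return sets
    if n_leads == 3:
        return [LeadSet(("I", "II", v), _DERIVED_II_NOTE) for v in PRECORDIAL_LEADS]
    if n_leads == 4:
        return [
            LeadSet(("I", "II", va, vb), _DERIVED_II_NOTE)
            for va in ("V1", "V2", "V3")
            for vb in ("V4", "V5", "V6")
        ]
    if n_leads == 12:
        return [LeadSet(LEAD_NAMES, "all leads, slot-synchronous in groups of 3")]
    raise LeadAlgebraError(
        f"n_leads must be one of 1, 2, 3, 4, 12; got {n_leads}"
    )


def all_lead_sets() -> list[LeadSet]:
    """Every tested lead set (12-, 4-, 3-, 2- and single-lead)."""
    out: list[LeadSet] = []
    for n in (12, 4, 3, 2, 1):
        out.extend(enumerate_lead_sets(n))
    return out


@dataclass(frozen=True)
class LeadSegment:
    """A 2.5 s single-lead segment with its acquisition offset."""

    lead: str
    samples: np.ndarray
    offset: float


def _complete_signals(record: EcgRecord) -> dict[str, np.ndarray]:
    """Record signals with limb leads filled in by reconstruction if possible."""
    signals = dict(record.signals)
    missing_limb = [l for l in LIMB_LEADS if l not in signals]
    present_limb = [l for l in LIMB_LEADS if l in signals]
    if missing_limb and len(present_limb) >= 2:
        rec = reconstruct_limb_leads(
            {l: signals[l] for l in present_limb[:2]}
        )
        for l in missing_limb:
            signals[l] = rec[l]
    return signals


def slice_asynchronous(
    record: EcgRecord, lead_set: LeadSet
) -> list[LeadSegment]:
    """Cut a record into per-lead 2.5 s segments at each lead's slot offset.

    In an asynchronous 2-/3-/4-lead set, lead II is not taken from slot 0:
    it is computed sample-wise from the slot-1 augmented leads
    (II = 2(aVF - aVR)/3) and carries the slot-1 offset, so the set stays
    completely asynchronous.
    """
    fs = record.sampling_rate
    seg_len = int(round(SLOT_DURATION * fs))
    signals = _complete_signals(record)

    def window(sig: np.ndarray, offset: float) -> np.ndarray:
        start = int(round(offset * fs))
        if start + seg_len > len(sig):
            raise LeadAlgebraError(
                f"record too short for offset {offset} s "
                f"({len(sig)} samples at {fs} Hz)"
            )
        return np.asarray(sig[start : start + seg_len])

    segments = []
    for lead in lead_set.leads:
        if lead == "II" and lead_set.is_asynchronous_subset:
            for need in ("aVR", "aVF"):
                if need not in signals:
                    raise MissingLeadError(
                        f"lead {need} missing; cannot derive slot-1 lead II"
                    )
            offset = DEFAULT_LAYOUT.offset_of("aVR")
            sig = derived_lead_ii(signals["aVR"], signals["aVF"])
        else:
            if lead not in signals:
                raise MissingLeadError(f"lead {lead} missing from record")
            offset = record.lead_offsets.get(lead, DEFAULT_LAYOUT.offset_of(lead))
            sig = signals[lead]
        segments.append(LeadSegment(lead, window(sig, offset), offset))
    return segments


def lead_set_to_mask(lead_set: LeadSet) -> np.ndarray:
    """Boolean availability vector (length 12, canonical order) for a set."""
    mask = np.zeros(len(LEAD_NAMES), dtype=bool)
    for lead in lead_set.leads:
        mask[LEAD_NAMES.index(lead)] = True
    return mask


def prepare_model_input(
    record: EcgRecord, lead_set: LeadSet
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the (12, n_samples) model input and availability mask.

    Rows follow the canonical lead order; leads outside the set are zero
    (the classifier ignores them by construction — they are masked out of
    the attention matrices and their fused rows are zeroed).
    """
    seg_len = int(round(SLOT_DURATION * record.sampling_rate))
    x = np.zeros((len(LEAD_NAMES), seg_len), dtype=np.float32)
    for seg in slice_asynchronous(record, lead_set):
        x[LEAD_NAMES.index(seg.lead)] = seg.samples
    return x, lead_set_to_mask(lead_set)


def records_to_tensor(
    records: Sequence[EcgRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack full 12-lead slot segments of many records into (n, 12, L)."""
    full = enumerate_lead_sets(12)[0]
    xs = [prepare_model_input(r, full)[0] for r in records]
    y = np.array([r.label for r in records], dtype=np.float32)
    return np.stack(xs), y
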