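"""Synthetic slot-asynchronous 12-lead ECG records and visit tables.

The generator drives every test and demo in this package.  A beat train is
built from a P-QRS-T template realized as a time-varying 3-component cardiac
dipole; each lead is a fixed linear projection of that dipole.  The limb-lead
projection vectors are constructed from the (I, II) frontal-plane pair via the
Einthoven/Goldberger relations, so the six limb leads satisfy the identities
*exactly* before noise — which is what makes the lead-algebra round-trip
tests possible.

Positives (acute myocardial infarction) receive an ST-segment dipole
component during the ST window of every beat, pointed at one of three
coronary territories (anterior, inferior, lateral) and calibrated so the
representative territory lead deviates by ``st_shift`` millivolts.  Because
the injury current is a dipole, reciprocal ST depression appears in the
electrically opposing leads, as on a real infarct ECG (for the inferior
territory, aVL and aVR move by -st_shift/2).  This is textbook
electrophysiology at cartoon fidelity, not a validated simulator: it exists
so that lead-count effects are testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .cohort import VisitRecord
from .leads import (
    LEAD_NAMES,
    EcgRecord,
    default_lead_offsets,
)

TERRITORIES = ("anterior", "inferior", "lateral")

#: leads whose ST segment deviates for each territory
TERRITORY_LEADS = {
    "anterior": ("V1", "V2", "V3", "V4"),
    "inferior": ("II", "III", "aVF"),
    "lateral": ("I", "aVL", "V5", "V6"),
}

# Frontal-plane unit vectors of the two basis limb leads (x right->left,
# y cranio-caudal); z is the anterior-posterior axis seen by the precordials.
_E_I = np.array([1.0, 0.0, 0.0])
_E_II = np.array([0.5, np.sqrt(3) / 2, 0.0])

# Precordial projection directions sweep the horizontal (x-z) plane from the
# right sternal border (V1, mostly posterior-facing electrode => anterior
# dipole projects negatively) around to the left lateral wall (V6 ~ lead I).
_PRECORDIAL_ANGLES = np.deg2rad([120.0, 95.0, 70.0, 45.0, 20.0, 0.0])


def _lead_matrix() -> np.ndarray:
    """12x3 projection matrix: signals = M @ dipole, canonical lead order."""
    m = np.zeros((12, 3))
    m[LEAD_NAMES.index("I")] = _E_I
    m[LEAD_NAMES.index("II")] = _E_II
    m[LEAD_NAMES.index("III")] = _E_II - _E_I
    m[LEAD_NAMES.index("aVR")] = -(_E_I + _E_II) / 2
    m[LEAD_NAMES.index("aVL")] = _E_I - _E_II / 2
    m[LEAD_NAMES.index("aVF")] = _E_II - _E_I / 2
    for i, ang in enumerate(_PRECORDIAL_ANGLES):
        m[LEAD_NAMES.index(f"V{i + 1}")] = [np.cos(ang), 0.0, np.sin(ang)]
    return m


LEAD_MATRIX = _lead_matrix()


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    ``st_shift`` is the ST deviation (mV) of the representative territory
    lead in positives; ``noise_sd`` is per-lead additive white noise (mV)
    applied after projection, so measured leads carry independent noise and
    the limb-lead identities hold exactly only at ``noise_sd = 0``.
    Records are generated at ``sampling_rate`` (500 Hz, the report rate)
    and decimated to ``output_rate`` (250 Hz, the model input rate).
    """

    n_records: int = 1000
    prevalence: float = 0.0178
    heart_rate_range: tuple[float, float] = (55.0, 95.0)
    st_shift: float = 0.2
    territory_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)
    noise_sd: float = 0.05
    sampling_rate: float = 500.0
    output_rate: float = 250.0
    duration: float = 10.0
    repeat_subject_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.st_shift < 0:
            raise ValueError("st_shift must be non-negative")
        if abs(sum(self.territory_probs) - 1.0) > 1e-9:
            raise ValueError("territory_probs must sum to 1")


# Beat template: (center s, width s, amplitude mV, direction) per wave.
# QRS is a Q-R-S triplet along the mean electrical axis (~55 deg frontal,
# tilted anteriorly); P and T are broader, lower bumps near the same axis.
_AXIS = np.array([0.55, 0.75, 0.35])
_AXIS = _AXIS / np.linalg.norm(_AXIS)
_T_DIR = np.array([0.65, 0.65, 0.40])
_T_DIR = _T_DIR / np.linalg.norm(_T_DIR)
_WAVES = (
    (0.10, 0.022, 0.12, _AXIS),    # P
    (0.225, 0.009, -0.18, _AXIS),  # Q
    (0.25, 0.011, 1.35, _AXIS),    # R
    (0.275, 0.009, -0.30, _AXIS),  # S
    (0.45, 0.050, 0.35, _T_DIR),   # T
)
_ST_WINDOW = (0.30, 0.40)  # seconds after beat onset, between S and T


def st_direction(territory: str) -> np.ndarray:
    """Unit injury-current direction for a territory.

    Calibrated targets: inferior -> lead aVF; anterior -> mean of V1-V4;
    lateral -> mean of I, aVL, V5, V6.  The returned vector is scaled so the
    calibration projection equals 1, i.e. multiplying by ``st_shift`` yields
    exactly ``st_shift`` mV in the representative lead(s).
    """
    if territory not in TERRITORIES:
        raise ValueError(f"unknown territory {territory!r}")
    idx = [LEAD_NAMES.index(l) for l in TERRITORY_LEADS[territory]]
    if territory == "inferior":
        u = LEAD_MATRIX[LEAD_NAMES.index("aVF")]
        cal_rows = LEAD_MATRIX[[LEAD_NAMES.index("aVF")]]
    else:
        u = LEAD_MATRIX[idx].mean(axis=0)
        cal_rows = LEAD_MATRIX[idx]
    u = u / np.linalg.norm(u)
    scale = float((cal_rows @ u).mean())
    return u / scale


def _st_bump(t: np.ndarray, onset: float) -> np.ndarray:
    """Smooth plateau over the ST window of one beat (raised-cosine edges)."""
    a, b = _ST_WINDOW
    ramp = 0.02
    x = t - onset
    up = 0.5 * (1 - np.cos(np.pi * np.clip((x - a) / ramp, 0, 1)))
    down = 0.5 * (1 + np.cos(np.pi * np.clip((x - b + ramp) / ramp, 0, 1)))
    return np.where(x < a, 0.0, np.where(x < b, np.minimum(up, down), 0.0))


def dipole_trace(
    t: np.ndarray,
    heart_rate: float,
    amp_scale: float = 1.0,
    st_vector: Optional[np.ndarray] = None,
) -> np.ndarray:
    """The 3-component cardiac dipole sampled at times ``t`` (shape (3, T))."""
    period = 60.0 / heart_rate
    d = np.zeros((3, t.size))
    n_beats = int(np.ceil(t[-1] / period)) + 1
    for k in range(n_beats):
        onset = k * period
        for center, width, amp, direction in _WAVES:
            g = np.exp(-0.5 * ((t - onset - center) / width) ** 2)
            d += amp_scale * amp * np.outer(direction, g)
        if st_vector is not None:
            d += np.outer(st_vector, _st_bump(t, onset))
    return d


def generate_record(
    config: SynthConfig,
    rng: np.random.Generator,
    label: int,
    territory: Optional[str] = None,
    subject_id: str = "",
    record_id: str = "",
) -> EcgRecord:
    """Generate one 10 s slot-asynchronous 12-lead record.

    The full 10 s projection is stored for every lead; asynchrony lives in
    the per-lead slot offsets, exactly as in a printed report where each
    lead's visible strip is its slot window of an ongoing recording.
    """
    fs = config.sampling_rate
    t = np.arange(int(round(config.duration * fs))) / fs
    heart_rate = rng.uniform(*config.heart_rate_range)
    amp_scale = rng.uniform(0.85, 1.15)
    st_vec = None
    if label == 1:
        if territory is None:
            territory = TERRITORIES[
                rng.choice(len(TERRITORIES), p=config.territory_probs)
            ]
        st_vec = config.st_shift * st_direction(territory)
    d = dipole_trace(t, heart_rate, amp_scale, st_vec)
    signals_500 = LEAD_MATRIX @ d  # (12, T), identities exact by construction
    if config.noise_sd > 0:
        signals_500 = signals_500 + rng.normal(
            0.0, config.noise_sd, signals_500.shape
        )
    factor = int(round(fs / config.output_rate))
    if factor > 1:
        # low-pass + decimation, zero-phase so beat timing is preserved
        signals = sps.decimate(signals_500, factor, ftype="fir", zero_phase=True)
    else:
        signals = signals_500
    return EcgRecord(
        signals={lead: signals[i] for i, lead in enumerate(LEAD_NAMES)},
        sampling_rate=config.output_rate,
        lead_offsets=default_lead_offsets(),
        label=int(label),
        subject_id=subject_id,
        record_id=record_id,
    )


def generate_dataset(config: SynthConfig) -> list[EcgRecord]:
    """Generate a dataset with an exact positive count.

    Positive count = round(prevalence * n_records); positives' territories
    are drawn from ``territory_probs``.  A fraction of records share a
    subject with an earlier record so that patient-level splitting is
    exercised.
    """
    rng = np.random.default_rng(config.seed)
    n_pos = int(round(config.prevalence * config.n_records))
    labels = np.zeros(config.n_records, dtype=int)
    labels[rng.choice(config.n_records, size=n_pos, replace=False)] = 1
    records = []
    subjects: list[str] = []
    for i in range(config.n_records):
        if subjects and rng.random() < config.repeat_subject_prob:
            subject = subjects[rng.integers(len(subjects))]
        else:
            subject = f"S{i:06d}"
        subjects.append(subject)
        records.append(
            generate_record(
                config,
                rng,
                int(labels[i]),
                subject_id=subject,
                record_id=f"R{i:06d}",
            )
        )
    return records


@dataclass
class VisitConfig:
    """Controls for the synthetic emergency-room visit table.

    Fractions let every labeling/exclusion rule fire: AMI-coded visits with
    null or out-of-window code-registration times, under-age patients, and
    ECGs recorded beyond the 24 h visit window.
    """

    n_visits: int = 200
    frac_ami: float = 0.1
    frac_null_registration: float = 0.1
    frac_out_of_window_registration: float = 0.1
    frac_under_20: float = 0.05
    frac_ecg_out_of_window: float = 0.05
    ecgs_per_visit: int = 1
    seed: int = 0

    ami_codes: tuple[str, ...] = ("I21", "I21.0", "I21.4", "I22", "I22.1")
    other_codes: tuple[str, ...] = ("I50", "J18.9", "K35", "R07.4", "S72.0")


def generate_visit_table(config: VisitConfig) -> list[VisitRecord]:
    """Synthetic visit/diagnosis table feeding the cohort labeling rules."""
    rng = np.random.default_rng(config.seed)
    t0 = datetime(2017, 1, 1)
    visits = []
    for i in range(config.n_visits):
        visit_time = t0 + timedelta(hours=float(rng.uniform(0, 24 * 365)))
        age = 19.0 if rng.random() < config.frac_under_20 else float(
            rng.uniform(20, 90)
        )
        if rng.random() < config.frac_ecg_out_of_window:
            ecg_dt = timedelta(hours=float(rng.uniform(25, 72)))
        else:
            ecg_dt = timedelta(hours=float(rng.uniform(0, 24)))
        ecg_times = [
            visit_time + ecg_dt for _ in range(config.ecgs_per_visit)
        ]
        diagnoses: list[tuple[str, Optional[datetime]]] = []
        if rng.random() < config.frac_ami:
            code = config.ami_codes[rng.integers(len(config.ami_codes))]
            u = rng.random()
            if u < config.frac_null_registration:
                reg: Optional[datetime] = None
            elif u < config.frac_null_registration + config.frac_out_of_window_registration:
                reg = ecg_times[0] + timedelta(hours=float(rng.uniform(25, 100)))
            else:
                reg = ecg_times[0] + timedelta(hours=float(rng.uniform(-12, 12)))
            diagnoses.append((code, reg))
        diagnoses.append(
            (config.other_codes[rng.integers(len(config.other_codes))], visit_time)
        )
        visits.append(
            VisitRecord(
                subject_id=f"P{i:05d}",
                visit_time=visit_time,
                age=age,
                diagnoses=diagnoses,
                ecg_times=ecg_times,
            )
        )
    return visits
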