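"""Record serialization: JSON sidecar + CSV sample table per record.

One record is stored as ``<stem>.json`` (lead names, per-lead offsets,
sampling rate, label, interpretation text, identifiers) plus ``<stem>.csv``
(one column per lead, millivolts).  A dataset directory additionally holds
``manifest.csv`` with one row per record.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .leads import EcgRecord


def save_record(record: EcgRecord, stem: str | Path) -> None:
    stem = Path(stem)
    meta = {
        "record_id": record.record_id,
        "subject_id": record.subject_id,
        "sampling_rate": record.sampling_rate,
        "label": record.label,
        "interpretation_text": record.interpretation_text,
        "leads": list(record.signals),
        "lead_offsets": record.lead_offsets,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame(
        {lead: np.asarray(sig) for lead, sig in record.signals.items()}
    ).to_csv(stem.with_suffix(".csv"), index=False, float_format="%.6f")


def load_record(stem: str | Path) -> EcgRecord:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".csv"))
    return EcgRecord(
        signals={lead: df[lead].to_numpy() for lead in meta["leads"]},
        sampling_rate=meta["sampling_rate"],
        lead_offsets=meta["lead_offsets"],
        label=meta["label"],
        interpretation_text=meta.get("interpretation_text"),
        subject_id=meta.get("subject_id", ""),
        record_id=meta.get("record_id", ""),
    )


def save_dataset(records: Sequence[EcgRecord], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        save_record(rec, directory / rec.record_id)
        rows.append(
            {
                "record_id": rec.record_id,
                "subject_id": rec.subject_id,
                "label": rec.label,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def load_dataset(directory: str | Path) -> list[EcgRecord]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    return [
        load_record(directory / rid) for rid in manifest["record_id"]
    ]
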