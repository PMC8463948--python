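"""Enumerate the tested asynchronous lead sets and slice a record.

2-/3-/4-lead sets are completely asynchronous (one lead per 2.5 s report
slot); lead II inside them is derived from the slot-1 augmented leads, so
it carries the 2.5 s offset rather than slot 0's.
"""

import numpy as np

from asyncecg import (
    LeadSet,
    SynthConfig,
    enumerate_lead_sets,
    generate_record,
    slice_asynchronous,
)

for n in (1, 2, 3, 4, 12):
    sets = enumerate_lead_sets(n)
    print(f"{n:>2}-lead sets ({len(sets)}):", ", ".join(str(s) for s in sets))

rec = generate_record(SynthConfig(), np.random.default_rng(1), label=0)
print("\nSlicing the 4-lead set I+II+V1+V4 (2.5 s per lead):")
for seg in slice_asynchronous(rec, LeadSet(("I", "II", "V1", "V4"))):
    print(f"  {seg.lead:>3}: {len(seg.samples)} samples at offset {seg.offset} s")
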