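"""Apply the ICD-10 labeling and exclusion rules to a synthetic visit table.

Visits with an I21/I22 code registered within 24 h of the ECG are labeled
positive; null or out-of-window registrations are excluded (never
relabeled); under-20 patients and ECGs beyond 24 h of the visit are
excluded.  The exclusion log itemizes every reason.
"""

from collections import Counter

from asyncecg import VisitConfig, generate_visit_table, label_and_filter, prevalence

visits = generate_visit_table(VisitConfig(n_visits=400, seed=5))
kept, excluded = label_and_filter(visits)

print(f"visits: {len(visits)}, ECGs kept: {len(kept)}, excluded: {len(excluded)}")
print(f"prevalence among kept ECGs: {100 * prevalence(kept):.2f}%")
print("exclusion reasons:")
for reason, count in Counter(e.reason for e in excluded).items():
    print(f"  {reason}: {count}")
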