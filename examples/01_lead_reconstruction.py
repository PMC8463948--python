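"""Recover all six limb leads from any two of them.

Einthoven's law (II = I + III) and the Goldberger relations make the six
limb leads a rank-2 linear system — the reason a smartwatch only ever needs
to measure two limb positions.
"""

import numpy as np

from asyncecg import reconstruct_limb_leads

# one sample per lead is enough to show the algebra
out = reconstruct_limb_leads({"I": np.array([1.0]), "III": np.array([0.5])})
for lead, sig in out.items():
    print(f"{lead:>4}: {sig[0]: .3f} mV")
print("Einthoven I + III - II =", out["I"][0] + out["III"][0] - out["II"][0])
print("Goldberger aVR+aVL+aVF =", out["aVR"][0] + out["aVL"][0] + out["aVF"][0])
# Expected: II = 1.5, aVR = -1.25, aVL = 0.25, aVF = 1.0, both residuals 0.
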