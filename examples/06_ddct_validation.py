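"""qPCR validation by the comparative-CT (2^-ddCt) method.

A gene measured in a target and a calibrator sample, normalized to a
reference gene (ACTIN-style), replicates averaged before differencing.
"""

import pandas as pd

from azkit.validation import CtTable, ddct

rows = [
    ("LeEXP1", "LAZ", 1, 22.1), ("LeEXP1", "LAZ", 2, 22.3),
    ("LeEXP1", "FAZ", 1, 26.0), ("LeEXP1", "FAZ", 2, 26.2),
    ("ACTIN", "LAZ", 1, 19.0), ("ACTIN", "LAZ", 2, 19.2),
    ("ACTIN", "FAZ", 1, 19.1), ("ACTIN", "FAZ", 2, 18.9),
]
table = CtTable(pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"]), "ACTIN")

rel = ddct(table, "LeEXP1", target_sample="LAZ", calibrator_sample="FAZ")
print(f"LeEXP1 relative expression LAZ vs FAZ: {rel:.2f}")
print(f"self-calibration (LAZ vs LAZ): {ddct(table, 'LeEXP1', 'LAZ', 'LAZ'):.2f}")

# A value of ~16 means ddCt = -4: the gene sits ~4 cycles closer to the
# reference in the LAZ than in the FAZ, i.e. ~2^4-fold higher expression.
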