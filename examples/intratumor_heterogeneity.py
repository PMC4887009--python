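"""Intra-tumor heterogeneity: do repeated biopsies classify consistently?

Simulates eight tumors with 2-3 biopsies each (within-tumor SD 0.3 vs
between-tumor SD 1.5 log2 units for the STC2 target), normalizes with the
reference trio, splits at the 67th-percentile -dCq cut, and reports the
fraction of tumors whose biopsies all land on the same side.
"""

import numpy as np

from refstab import SimConfig, simulate_heterogeneity
from refstab.qc import collapse_replicates, delta_cq
from refstab.validation import heterogeneity_concordance

TRIO = ["CHCHD1", "SRSF9", "TMBIM6"]

cq, tumor_ids, _ = simulate_heterogeneity(SimConfig(seed=1))
ndcq = delta_cq(collapse_replicates(cq), TRIO)
values = ndcq.values.loc["STC2"]
cut = float(np.percentile(values.dropna(), 67))
result = heterogeneity_concordance(values, tumor_ids, cut)

print(f"tertile cut on -dCq(STC2): {cut:.2f}")
for tumor, ok in result.per_tumor.items():
    biopsies = values[tumor_ids == tumor].round(2).to_dict()
    print(f"  {tumor}: {'concordant ' if ok else 'DISCORDANT'}  {biopsies}")
print(f"\nfraction of multi-biopsy tumors concordant: {result.fraction_concordant:.2f}")
print("Concordant tumors classify identically from any single biopsy; discordant"
      "\nones sit close to the cut, where intra-tumor variability flips the label.")
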