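"""Simulate a 74-patient qPCR cohort and rank candidate reference genes.

Generates duplicate-replicate Cq data for nine candidates (three planted
stable), collapses replicates with QC, and runs geNorm stepwise exclusion
plus NormFinder.  Low M / low stability value = more stable; the
pairwise-variation series V_n/n+1 decides how many reference genes the
normalization factor needs (V < 0.15 means the extra gene is redundant).
"""

from refstab import SimConfig, rank_candidates, simulate_cohort

CANDIDATES = ["CHCHD1", "GNB2L1", "IPO8", "LASP1", "RPL27A", "RPS12", "SOD1", "SRSF9", "TMBIM6"]

cohort = simulate_cohort(SimConfig(seed=1))
analysis = rank_candidates(cohort.cq, candidates=CANDIDATES)

print("geNorm stepwise exclusion (remaining genes -> average M):")
for step in analysis.genorm.trace:
    removed = f"  removed {step.removed} (M={step.removed_m:.3f})" if step.removed else "  final pair"
    print(f"  n={len(step.remaining):d}  avg M={step.average_m:.3f}{removed}")

print("\npairwise variation series:")
for n, v in analysis.genorm.pairwise_variation:
    print(f"  V_{n}/{n + 1} = {v:.3f}")

print(f"\nselected reference set: {analysis.optimal_set.genes} "
      f"(V={analysis.optimal_set.v:.3f} < {analysis.optimal_set.cutoff})")
print(f"NormFinder ranking (most->least stable): {analysis.normfinder.ranking}")
print("\nBoth methods should place the planted-stable trio CHCHD1/SRSF9/TMBIM6 on top.")
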