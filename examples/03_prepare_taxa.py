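"""Centred log-ratio transform and prevalence filtering of a taxa count table.

Counts are compositional: only relative information survives sequencing.
The CLR (log of each taxon over the sample's geometric mean, pseudo-count
0.5) maps them to real values whose rows sum to zero.
"""
import numpy as np

from medigut import SimulationConfig, clr_transform, filter_by_prevalence, generate_cohort

cohort = generate_cohort(SimulationConfig(seed=3))
counts = cohort.counts

clr = clr_transform(counts, pseudo=0.5)
print(f"CLR table: {clr.shape[0]} samples x {clr.shape[1]} taxa")
print(f"max |row sum| = {np.abs(clr.sum(axis=1)).max():.2e}  (identically 0 in exact arithmetic)")

retained = filter_by_prevalence(counts, min_rel=1e-4, min_frac_samples=0.10)
print(f"taxa at >=0.01% relative abundance in >=10% of samples: "
      f"{len(retained)}/{counts.shape[1]}")
print("only retained taxa are carried into the association screens; the CLR "
      "itself is always computed over the full table")
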