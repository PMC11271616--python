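"""Generate a synthetic case-control cohort and inspect its ground truth.

The generator emulates the post-bioinformatics state of a pediatric
case-control diet-microbiome study: participant metadata, FFQ intakes,
and a stool taxa count table, all driven by a latent diet-healthfulness
with known diet->taxa->disease effects.
"""
import numpy as np
from scipy.stats import spearmanr

from medigut import SimulationConfig, generate_cohort

cfg = SimulationConfig(n_cases=44, n_controls=51, seed=1)
cohort = generate_cohort(cfg, compute_oracles=True)

print(f"participants: {len(cohort.participants)} "
      f"({(cohort.participants['status'] == 1).sum()} cases)")
print(f"stool samples: {cohort.counts.shape[0]} x {cohort.counts.shape[1]} taxa")

merged = cohort.ffq.merge(cohort.truth.amed_true.rename("amed"),
                          left_on="participant_id", right_index=True)
rho = spearmanr(merged["fiber"], merged["amed"]).statistic
print(f"Spearman rho(fiber, aMED) = {rho:.2f}  "
      "(calibrated toward the ~0.7 seen in real adolescent cohorts)")

active = np.flatnonzero(cohort.truth.gamma * cohort.truth.b)
for j in active:
    print(f"taxon {j}: gamma={cohort.truth.gamma[j]:+.1f}, b={cohort.truth.b[j]:+.1f}, "
          f"true ACME={cohort.truth.oracle_acme_diff[j]:+.4f}")
print("the true ACME is the probability-scale change in disease risk carried "
      "through that taxon when the diet score moves from 0 to 1")
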