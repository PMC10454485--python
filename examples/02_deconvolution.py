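"""Estimate immune-cell fractions from whole-blood beta values.

Constrained projection onto the six cell-type signature profiles, then a
Welch t-test per cell type comparing cases and controls.
"""

import numpy as np

from bloodewas import SimConfig, compare_fractions, estimate_fractions, generate_cohort
from bloodewas.datamodel import BetaMatrix

cohort = generate_cohort(SimConfig(seed=2))

mask = np.isin(cohort.reference.cpg_ids, cohort.signature_cpgs)
reference = BetaMatrix(cohort.reference.values[mask],
                       cohort.reference.cpg_ids[mask],
                       cohort.reference.sample_ids)
fractions = estimate_fractions(cohort.beta, reference)

err = fractions.table.to_numpy() - cohort.truth.true_fractions.to_numpy()
print(f"per-fraction RMSE vs truth: {np.sqrt((err ** 2).mean()):.4f}")
# RMSE well below 0.01 at the default noise level: the estimated
# fractions are accurate enough to serve as model covariates.

print("\ncase/control comparison per cell type:")
print(compare_fractions(fractions, cohort.meta.phenotype).to_string(index=False))
# Expect a significant NK decrease and CD4 increase in cases, with B
# cells and monocytes unchanged - the implanted group structure.
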