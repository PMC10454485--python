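# bloodewas

Whole-blood DNA methylation case–control analysis, built around the
question the field keeps asking of blood EWAS data: *is the methylation
signal of a disease genuine epigenetic risk, or is it a shadow of
genotype and cell composition?* The motivating application is multiple
sclerosis, where the major genetic risk haplotype (HLA-DRB1\*15:01,
tagged by rs3135388) is known to act partly through methylation, but the
toolkit is generic for any binary phenotype measured on Illumina-style
beta-value arrays.

The package provides, as a library:

- **Cell deconvolution** — constrained projection of each sample's beta
  profile onto six immune-cell reference profiles (B, NK, CD4⁺ T,
  CD8⁺ T, monocytes, neutrophils): non-negative least squares with a
  unit-sum constraint. Case/control comparison of the estimated
  fractions.
- **EWAS** — per-CpG logistic regression
  `phenotype ~ β_i + age + sex + cell fractions + region`, with Wald
  tests at the genome-wide threshold p < 9.8×10⁻⁸ and effect size
  Δβ = mean(case) − mean(control) flagged at |Δβ| > 0.02. DMR calling by
  Fisher's and Stouffer's combination plus the harmonic mean of
  BH-adjusted member p-values.
- **Genotype-risk correction** — the same model with the risk-haplotype
  dosage and a polygenic risk score (PRS) as covariates; CpGs whose
  association is genotype-driven lose significance.
- **Cell-type-specific DMPs** — per cell type,
  `M_i ~ f_k + f_k:phenotype + age + sex`; a csDMP needs an interaction
  estimate beyond ±2 (M-value units per fraction) and p < 9.8×10⁻⁸.
- **CIT mediation** — the four-condition causal inference test for
  genotype → methylation → disease, with a permutation equivalence test
  for the conditional-independence condition; omnibus p = max of the
  four components.
- **Risk scores and ROC** — grcMethScore_s = Σᵢ β_si·Δβᵢ over the
  genotype-corrected DMPs, PRS, tag-SNP dosage, combined logistic
  scores; AUC by Mann–Whitney pair counting with DeLong (or bootstrap)
  confidence intervals; Pearson correlations between scores.
- **cis-methQTL** — one-way ANOVA of β across genotype groups for every
  SNP within ±18 kb, Bonferroni within the window; bookkeeping of the
  fraction of DMPs modulated by genotype; Fisher-exact SNP association
  and Χ² risk-haplotype selection.
- **Synthetic cohorts** — a generator that emulates the statistical
  structure of such a study (cell mixtures, implanted cell-specific and
  whole-blood effects, methQTLs, a mediated risk haplotype of 3× odds,
  polygenic background) together with the ground truth, so every stage
  can be validated end to end.

## Worked example

```python
from bloodewas import SimConfig, generate_cohort, estimate_fractions, compare_fractions
from bloodewas.datamodel import BetaMatrix
import numpy as np

cohort = generate_cohort(SimConfig(seed=2))          # 600 samples, 2000 CpGs
mask = np.isin(cohort.reference.cpg_ids, cohort.signature_cpgs)
reference = BetaMatrix(cohort.reference.values[mask],
                       cohort.reference.cpg_ids[mask], cohort.reference.sample_ids)
fractions = estimate_fractions(cohort.beta, reference)
print(compare_fractions(fractions, cohort.meta.phenotype))
```

prints

```
cell_type  mean_case  mean_control  difference            p  degenerate
        B   0.059154      0.061683   -0.002529 9.414952e-02       False
       NK   0.021801      0.029963   -0.008162 5.283419e-15       False
     CD4T   0.083644      0.071655    0.011989 5.648134e-12       False
     CD8T   0.094004      0.107360   -0.013356 5.616123e-12       False
     Mono   0.088471      0.087741    0.000730 6.891252e-01       False
      Neu   0.652925      0.641598    0.011327 8.012056e-05       False
```

— the NK-cell deficit (0.022 vs 0.030) and CD4⁺ excess in cases are
recovered from the mixed profiles, while B cells and monocytes show no
group difference, matching the generating conditions. The
`examples/` directory has one short script per capability
(deconvolution, EWAS/DMRs, genetic-risk correction and scores, csDMPs,
CIT, methQTL); each prints its result with a note on what it means.

A full chain (simulate → QC → deconvolve → EWAS → corrected EWAS →
scores/ROC → csDMP → CIT → methQTL → report) is one call:

```bash
bloodewas run-all -o myrun --seed 1      # or: from bloodewas import run_all
cat myrun/report.md
```

Identical config and seed give byte-identical outputs; `manifest.json`
records seed, version and SHA-256 of every file.

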