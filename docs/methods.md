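# Methods

This note documents the statistical models implemented in `bloodewas`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Measurement scales

Methylation is carried as beta values β ∈ [0,1] (methylated fraction)
and transformed to M values, M = log₂(β/(1−β)), wherever a linear model
assumes roughly homoskedastic Gaussian errors. β is clipped to
[ε, 1−ε] with ε = 10⁻³ before the transform (|M| ≤ ~10); the inverse
β = 2^M/(1+2^M) round-trips to 10⁻¹⁰ away from the clip bounds.
Missing measurements are NaN; the transform refuses them, so missing
data must be filtered (or imputed upstream) before modelling. All
genomic coordinates are 1-based with closed intervals; BED export
converts to 0-based half-open on write.

## Quality control

Probes are dropped when their detection p-value exceeds the cut (default
0.01) in more than a configured fraction of samples (default 5%);
samples are dropped at >10% missing probes. The source pipelines for
array data delegate these two thresholds to their own defaults, so both
are config-exposed here. Genotype QC runs in a fixed order — SNP call
rate ≥ 98%, sample call rate ≥ 95%, then Hardy–Weinberg equilibrium —
with HWE as a 1-df chi-square on genotype counts (deterministic and
exactly testable; the exact test adds nothing at these sample sizes).
Monomorphic SNPs are untestable for HWE and are retained with a flag.
Missing dosages are excluded pairwise; no imputation. Probes on sex
chromosomes or near polymorphisms are deliberately *not* filtered.

## Cell deconvolution

Each sample's β over the signature CpGs is modelled as Σₖ fₖ·βₖ with
fₖ ≥ 0, Σfₖ = 1. The solver is Lawson–Hanson non-negative least squares
with the unit-sum constraint imposed as a strongly weighted equation,
then exact renormalization of the ~10⁻⁴ slack. This was chosen over the
simpler truncate-and-renormalize of an unconstrained fit because the
two diverge by up to ~0.007 in low-abundance fractions when negativity
actually binds, which is material when fractions near 0.02 (NK cells)
carry the group signal; the weighted-NNLS solution agrees with a
general QP solver to ~10⁻⁴ and is deterministic. An optional sign-free
intercept absorbs global shifts between sample and reference scale
(off by default; simulated data share the scale). Group comparison of
fractions is Welch's t by default (Wilcoxon selectable) — the underlying
study reports p-values without naming a test, and with n in the
hundreds the two agree in practice.

## EWAS

Per CpG: logistic regression of case/control status on β plus age, sex
dummies, region dummies and the estimated cell fractions; one fraction
(neutrophils, the largest) is dropped to break the sum-to-one
collinearity with the intercept. Inference is a Wald test on the β
coefficient; significance at the EWAS genome-wide threshold
p < 9.8×10⁻⁸ and a separate large-effect flag at |Δβ| > 0.02, where
Δβ is the raw case-minus-control mean (positive = hypermethylated in
cases). Perfect separation and non-convergence are flagged as
non-estimable with p = NaN — never a spurious zero — and a failing CpG
never aborts a scan. The genotype-risk-corrected EWAS adds the
risk-haplotype dosage and the PRS as covariates.

The fits use an in-package IRLS Newton solver with a small ridge
safeguard (~10⁻¹²) because a scan multiplies ~10³–10⁵ small GLMs;
coefficients, standard errors and p-values are cross-checked against
statsmodels on fixtures in the unit tests. Batch is accepted as an
optional covariate but off by default.

DMRs: candidate regions are maximal runs of tested CpGs on one
chromosome with inter-CpG gaps ≤ 1000 bp and ≥ 3 members (both
config-exposed; region definition is this package's own, since upstream
pipelines delegate it). Each region is summarized three ways — Fisher's
combination (−2Σln p, χ²₂ₖ), Stouffer's Z from one-sided z-transforms,
and the harmonic mean of BH-adjusted member p-values — and is
significant only if all three are ≤ 0.05. BH is used wherever an FDR is
needed. Member p-values of 0 are clipped at 10⁻³⁰⁰ and flagged. The
"Fisher" component is the p-value combination method: an exact
contingency test has no role in combining per-CpG p-values, and the
combination reading is the only one that type-checks.

Sensitivity analysis: per CpG, a numeric covariate gets a simple
regression slope test, a categorical one a one-way ANOVA, both with R²
reported. Expression–methylation coupling is Pearson's R with a t-based
p, refusing zero-variance input rather than returning NaN.

## Cell-type-specific DMPs

Per cell type k and CpG i (on the M scale):

    M_i ~ f_k + f_k:phenotype + age + sex

by OLS, with a t-test on the interaction coefficient. A csDMP requires
|estimate| > 2 and p < 9.8×10⁻⁸; direction is the estimate's sign. The
deliberate omissions: no phenotype main effect (the model follows the
printed per-cell-type form literally; a config flag can add one) and no
other cell fractions in the design — fitting one small model per cell
type is precisely the adaptation that avoids the overburdened joint
interaction model. The joint model is kept only as a comparison at
small scale in tests. M values rather than β avoid the
fraction-dependent variance bias of β-scale interaction fits.

Two scale caveats, both visible in the synthetic runs:

* The ±2 cut is in M-units per unit fraction. Since dM/dβ =
  1/(ln2·β(1−β)) ≤ ~5.8 at mid-range β, a within-cell-type shift of
  Δβ = 0.15 only exceeds the cut when the CpG's baseline is extreme
  (β ≲ 0.12 or ≳ 0.88). The simulator therefore implants cell-specific
  effects at baselines 0.08/0.92 — consistent with disease DMPs at
  regulatory CpGs, which sit near the methylation extremes.
* A uniform whole-blood case shift loads onto f_k:phenotype for
  *small*-fraction cell types (the regressor ≈ fraction × phenotype is
  nearly proportional to phenotype, and there is no main effect to
  absorb it), so environmental DMPs can surface as csDMPs of NK or B
  cells. This is a property of the published model form, not an
  implementation artifact; the summary bookkeeping makes it visible
  rather than hiding it.

## CIT mediation

For locus L (dosage), candidate mediator G (β) and binary trait T, four
component p-values: (1) T~L (logistic Wald); (2) L~G adjusted for T
(linear); (3) T~G adjusted for L (logistic); (4) an equivalence test of
L ⊥ T | G. Condition (4) compares the observed Wald χ² of L in
T ~ G + L against B surrogate statistics computed with
G\* = fitted(G~L) + permuted residuals — surrogates that preserve the
L–G relationship but, by construction, carry no information about T
beyond L. Under full mediation the observed statistic falls in the
lower tail; p₄ = (1 + #{F\* ≤ F_obs})/(B+1). The omnibus p is the
maximum of the four, so every link must hold; B defaults to 500, and
the test is deterministic given its seed. A cheaper F-approximation for
condition (4) exists behind a flag but is never the default — it tests
the wrong null. In the pipeline, CIT runs on the index CpG (lowest
EWAS p) of each significant DMR against the risk-haplotype tag-SNP
dosage; haplotype phasing is out of scope, the tag SNP *is* the
haplotype here. Risk-haplotype selection from haplotype count tables is
a per-haplotype 2×2 χ² (this haplotype vs all others × case/control),
Yates-corrected when an expected cell is < 5, ties broken
lexicographically and flagged.

## Risk scores and ROC

grcMethScore_s = Σᵢ β_si·Δβᵢ over the DMPs that survive genetic-risk
correction, with Δβ weights taken from that corrected scan. PRS is the
weighted dosage sum with externally supplied (or simulated) per-SNP
log-ORs; the haplotype score is the tag-SNP dosage itself, with missing
calls flagged rather than zeroed. Combined scores come from a logistic
fit. AUC is the tie-aware Mann–Whitney pair statistic; its CI is DeLong
by default (midrank structural components; no installed package
provides this, so it is implemented here) or a seeded bootstrap. In all
of the package's own assessments the weights are estimated on a
training split and AUC is reported both held-out and in-sample,
labeled — computing both on the full sample, as studies commonly do,
visibly inflates the methylation score's AUC. When a training split is
too small for any CpG to reach genome-wide significance, the score
falls back to the top-10 CpGs by p and says so in the output.

## cis-methQTL

For each tested CpG, SNPs within ±18 kb (closed bounds) on the same
chromosome enter a one-way ANOVA of β across dosage groups (groups with
< 2 samples are dropped; < 2 usable groups makes the pair untestable).
Significance policy: Bonferroni within the CpG's window (α/m),
config-switchable to nominal α — the study behind this design does not
state its policy, and the modulated fraction is monotone in whichever
is chosen. ANOVA is on β, matching the published model form. A DMP is
"modulated" when ≥ 1 tested SNP passes; the same machinery, without the
distance restriction, covers testing DMPs against the PRS SNP panel.

## Synthetic cohorts: what they emulate

Defaults are the package's standing study conditions; they emulate a
1:2 case-control whole-blood study at desk scale (600 samples, 2000
CpGs rather than ~7×10⁵ — problem sizes chosen so the full suite runs
in minutes on one CPU):

* **Fractions** per sample from group-specific Dirichlet distributions
  (concentration 200, tight blood-like variability). Group means: NK
  0.031→0.021, CD8⁺ 0.106→0.095, CD4⁺ 0.071→0.081 (control→case), B
  0.06 and monocytes 0.09 unchanged, neutrophils absorbing the rest.
* **Reference profiles**: per cell type, signature CpGs separated from
  all other types by ≥ 0.5 β; all other CpGs share one baseline across
  types, so composition changes do not move them.
* **Cell-specific case effects** (default 30 CpGs: B 12, Mono 8, CD4 5,
  CD8 3, NK 2, Neu 0; Δβ = 0.15 within the cell type's profile, half
  hyper at baseline 0.08, half hypo at 0.92) applied inside the profile
  before mixing — by linearity, identical to a Δβ·fₖ shift of case
  samples.
* **Whole-blood environmental effects**: 25 CpGs at Δβ = 0.02 with
  per-sample biological sd 0.03, independent of all genotypes; two of
  them also carry a cis SNP (0.03/allele), so a realistic minority
  (~5%) of corrected DMPs is genotype-modulated.
* **Risk haplotype**: tag-SNP MAF 0.15, total odds ratio 3 per allele.
  In chain mode the effect passes entirely through a cluster of four
  co-methylated mediator CpGs (0.2 β per allele, shared biological
  factor sd 0.06, idiosyncratic sd 0.01) — four CpGs because mediation
  was established on four DMR index CpGs in the motivating study, and a
  shared factor because DMR members co-methylate. Independent mode
  wires the haplotype to the phenotype directly (mediators remain
  methQTLs); reverse mode shifts the mediators by 0.05·phenotype with
  no methQTL link.
* **Polygenic background**: 201 SNPs (the non-MHC GWAS panel size of
  the motivating study), |log OR| ≤ 0.2 drawn log-normally, frequencies
  0.1–0.9. Cis methQTLs: 20 CpGs at 0.10 β per allele.
* **Noise**: Gaussian on the β scale, sd 0.01 (technical replicate
  scale for EPIC-class arrays), clipped to [0,1]; a moment-matched beta
  noise model is selectable. Phenotypes are drawn from the generating
  logistic model in a 3× pool and sampled to exact case/control counts
  (case-control ascertainment preserves odds ratios).

Determinism: one seeded generator drives everything; fixed seed ⇒
bit-identical cohorts, and the pipeline derives per-stage seeds from
the run seed, giving byte-identical output files.

What passing tests on these cohorts does **not** show: robustness to
array normalization and batch artifacts (no probe-type chemistry, no
batch structure is simulated), to LD between SNPs (none), to reference
mismatch in deconvolution (sample and reference share a scale), or to
the small effect sizes of real polygenic methylation signal — the
implanted effects are strong enough to be individually genome-wide
significant at n≈10³, which real whole-blood DMPs often are not. AUCs
on synthetic cohorts (~0.95 for the methylation score vs ~0.70 genetic)
are accordingly higher than any real study's; the validated property is
the *ordering* and the held-out evaluation, not the level.

## Numerical choices and degenerate inputs

Collinear design columns are dropped greedily (SVD rank test, tolerance
10⁻⁸ relative) with a warning; separation in logistic fits is detected
(fitted probabilities pinned to the data, or |η| diverging) and
reported as non-estimable. ANOVA with zero within-group variance and
unequal means reports the smallest representable p, flagged. Fisher's
exact odds ratio uses the Haldane–Anscombe 0.5 correction only when a
cell is zero. Score-vs-score correlation CIs use the Fisher z
transform. Ties in AUC count one half; ties in risk-haplotype selection
break lexicographically and are flagged.

## Limitations

Beyond the simulation caveats above: the per-cell-type csDMP model
inherits the scale-dependence of its published form (the ±2 cut is not
invariant to the fraction scale); CIT component tests assume the
logistic/linear forms given; the pipeline's PRS weights must be supplied
(no clumping/thresholding machinery); idat parsing, BMIQ normalization,
ComBat batch correction, epigenetic clocks and pathway analysis are out
of scope by design.
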