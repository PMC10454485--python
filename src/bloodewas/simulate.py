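"""Synthetic whole-blood methylation cohort generator.

Emulates the statistical structure of a case-control blood methylation
study: each sample's beta profile is a mixture of six immune-cell
reference profiles (B cells, NK cells, CD4+ and CD8+ T cells, monocytes,
neutrophils) drawn from group-specific Dirichlet fractions, with

* cell-type-specific case effects implanted inside one cell type's
  profile (the signal the per-cell-type interaction model must recover),
* whole-blood case/control effects independent of genotype (the signal a
  genotype-risk-corrected EWAS retains),
* cis-methQTLs shifting beta additively per risk-allele dosage,
* a tag-SNP "risk haplotype" of configurable odds ratio whose effect on
  disease is mediated by a cluster of co-methylated CpGs (chain mode), or
  direct (independent mode), or reversed (phenotype shifts methylation),
* a polygenic background of many small-effect SNPs.

Ground truth for every implanted signal is returned in :class:`SimTruth`
so recovery can be tested. Fixed seed implies bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, GenotypeTable, ProbeAnnotation, SampleMeta

__all__ = ["SimConfig", "SimTruth", "SimCohort", "generate_reference",
           "mix_profiles", "generate_cohort", "HLA_TAG_SNP"]

HLA_TAG_SNP = "rs3135388"  # tag SNP operationalizing the DRB1*15:01 risk haplotype

DEFAULT_CELL_TYPES = ("B", "NK", "CD4T", "CD8T", "Mono", "Neu")

# Group mean blood fractions. NK / CD8T / CD4T follow the case-control
# means reported for MS whole blood (NK 0.021/0.031, CD8 0.095/0.106,
# CD4 0.081/0.071); B cells and monocytes show no group difference and
# sit at typical blood proportions; neutrophils absorb the remainder.
DEFAULT_FRACTIONS_CONTROL = {
    "B": 0.060, "NK": 0.031, "CD4T": 0.071, "CD8T": 0.106, "Mono": 0.090,
    "Neu": 0.642,
}
DEFAULT_FRACTIONS_CASE = {
    "B": 0.060, "NK": 0.021, "CD4T": 0.081, "CD8T": 0.095, "Mono": 0.090,
    "Neu": 0.653,
}

DEFAULT_CELL_EFFECT_COUNTS = {"B": 12, "Mono": 8, "CD4T": 5, "CD8T": 3, "NK": 2, "Neu": 0}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults are desk-scale versions of the emulated study: a 1:2
    case-control cohort, six-cell-type mixtures with tight (blood-like)
    Dirichlet variability, implanted cell-specific effects concentrated in
    B cells and monocytes, a cluster of co-methylated mediator CpGs
    carrying the risk-haplotype effect, and a 201-SNP polygenic score.
    """

    n_cases: int = 200
    n_controls: int = 400
    n_cpgs: int = 2000
    cell_types: tuple = DEFAULT_CELL_TYPES
    fraction_means_control: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS_CONTROL))
    fraction_means_case: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS_CASE))
    dirichlet_concentration: float = 200.0

    # reference / signature structure
    n_signature_cpgs_per_type: int = 33
    signature_margin: float = 0.5

    # cell-type-specific case effects (applied within the named cell
    # type's profile; alternately hyper at a low baseline and hypo at a
    # high one so the effect is large on the M scale)
    cell_effect_counts: dict = field(default_factory=lambda: dict(DEFAULT_CELL_EFFECT_COUNTS))
    cell_effect_delta: float = 0.15
    effect_baseline_hyper: float = 0.08
    effect_baseline_hypo: float = 0.92

    # whole-blood, genotype-independent case effects (environmental signal);
    # a small subset additionally carries a cis-methQTL, so a realistic
    # minority of disease DMPs is genotype-modulated
    n_direct_cpgs: int = 25
    direct_effect_delta: float = 0.02
    direct_bio_sd: float = 0.03
    direct_baseline: float = 0.5
    n_direct_qtl_cpgs: int = 2
    direct_qtl_effect: float = 0.03

    # cis-methQTLs
    n_methqtl_cpgs: int = 20
    methqtl_effect: float = 0.10
    methqtl_baseline: float = 0.40

    # risk haplotype and its mediator CpG cluster
    n_mediator_cpgs: int = 4
    mediator_qtl_effect: float = 0.20
    mediator_baseline: float = 0.30
    mediator_shared_sd: float = 0.06   # co-methylation of the mediator cluster
    mediator_idio_sd: float = 0.01
    reverse_shift: float = 0.05        # T -> G shift in reverse mode
    risk_haplotype_or: float = 3.0
    hla_maf: float = 0.15

    # polygenic background
    n_prs_snps: int = 201
    prs_max_abs_logor: float = 0.2
    n_background_snps: int = 40

    mediation_mode: str = "chain"      # chain | independent | reverse
    noise_sd: float = 0.01
    noise_model: str = "gaussian"      # gaussian | beta
    seed: int = 0

    def __post_init__(self):
        if self.mediation_mode not in ("chain", "independent", "reverse"):
            raise ValueError(f"unknown mediation_mode {self.mediation_mode!r}")
        for means in (self.fraction_means_control, self.fraction_means_case):
            vals = np.array([means[c] for c in self.cell_types])
            if (vals < 0).any():
                raise ValueError("fraction means must be non-negative")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError("fraction means must sum to 1 per group")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_effect_cpgs(self) -> int:
        return int(sum(self.cell_effect_counts.values()))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth of every implanted signal (the recovery oracle)."""

    cell_effects: pd.DataFrame      # cpg_id, cell_type, delta_beta, affected_group
    direct_effects: pd.DataFrame    # cpg_id, delta_beta
    methqtl: pd.DataFrame           # cpg_id, snp_id, effect_per_allele
    mediator_cpgs: list
    mediation_mode: str
    true_fractions: pd.DataFrame    # sample x cell type
    prs_weights: pd.Series          # per-SNP true log-OR
    phenotype_coefficients: dict    # generating model coefficients


@dataclass
class SimCohort:
    beta: BetaMatrix
    genotypes: GenotypeTable
    meta: SampleMeta
    annotation: ProbeAnnotation
    reference: BetaMatrix           # CpG x cell type profiles
    signature_cpgs: np.ndarray
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# CpG index layout: deterministic allocation of implanted roles.


def _layout(config: SimConfig) -> dict:
    n_sig = config.n_signature_cpgs_per_type * len(config.cell_types)
    counts = [n_sig, config.n_effect_cpgs, config.n_direct_cpgs,
              config.n_methqtl_cpgs, config.n_mediator_cpgs]
    if sum(counts) > config.n_cpgs:
        raise ValueError(
            f"n_cpgs={config.n_cpgs} too small for "
            f"{sum(counts)} structured CpGs"
        )
    edges = np.cumsum([0] + counts)
    return {
        "signature": np.arange(edges[0], edges[1]),
        "cell_effect": np.arange(edges[1], edges[2]),
        "direct": np.arange(edges[2], edges[3]),
        "methqtl": np.arange(edges[3], edges[4]),
        "mediator": np.arange(edges[4], edges[5]),
        "null": np.arange(edges[5], config.n_cpgs),
    }


def _cpg_ids(n: int) -> np.ndarray:
    return np.array([f"cg{i:07d}" for i in range(n)], dtype=object)


def generate_reference(config: SimConfig, rng: np.random.Generator | None = None) -> BetaMatrix:
    """Cell-type reference profiles (CpG x cell type).

    Signature CpGs separate their own cell type from every other type by
    at least ``signature_margin`` on the beta scale; all remaining CpGs
    share one common baseline across cell types (drawn once), so mixing
    leaves them invariant to the cell composition.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    margin = config.signature_margin
    if not 0 < margin < 0.9:
        raise ValueError("signature margin must be in (0, 0.9)")
    lay = _layout(config)
    K = len(config.cell_types)
    baseline = rng.uniform(0.1, 0.9, size=config.n_cpgs)

    # override baselines of implanted CpGs so effects stay in [0,1] and
    # (for cell effects) are large on the M scale
    half = len(lay["cell_effect"]) // 2 + len(lay["cell_effect"]) % 2
    baseline[lay["cell_effect"][:half]] = config.effect_baseline_hyper
    baseline[lay["cell_effect"][half:]] = config.effect_baseline_hypo
    baseline[lay["direct"]] = config.direct_baseline
    baseline[lay["methqtl"]] = config.methqtl_baseline
    baseline[lay["mediator"]] = config.mediator_baseline

    ref = np.tile(baseline[:, None], (1, K))
    per = config.n_signature_cpgs_per_type
    for k in range(K):
        rows = lay["signature"][k * per:(k + 1) * per]
        low = rng.uniform(0.05, 0.95 - margin, size=len(rows))
        ref[rows, :] = low[:, None]
        ref[rows, k] = low + margin
    return BetaMatrix(ref, _cpg_ids(config.n_cpgs), np.asarray(config.cell_types, dtype=object))


def mix_profiles(
    reference: BetaMatrix,
    fractions: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    noise_model: str = "gaussian",
) -> BetaMatrix:
    """Mix cell-type profiles into sample profiles.

    beta_sample = sum_k f_k * beta_ref[:, k] plus measurement noise,
    clipped into [0, 1]. Rows of ``fractions`` (one per sample) must be
    non-negative and sum to 1.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.ndim != 2 or fr.shape[1] != reference.n_samples:
        raise ValueError("fractions must be (n_samples, n_cell_types)")
    if (fr < 0).any():
        raise ValueError("fractions must be non-negative")
    if np.abs(fr.sum(axis=1) - 1.0).max() > 1e-8:
        raise ValueError("fraction rows must sum to 1")
    vals = reference.values @ fr.T
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        vals = _add_noise(vals, noise_sd, rng, noise_model)
    vals = np.clip(vals, 0.0, 1.0)
    ids = np.array([f"S{j:05d}" for j in range(fr.shape[0])], dtype=object)
    return BetaMatrix(vals, reference.cpg_ids.copy(), ids)


def _add_noise(vals, noise_sd, rng, noise_model):
    if noise_model == "gaussian":
        return vals + rng.normal(0.0, noise_sd, size=vals.shape)
    if noise_model == "beta":
        # moment-matched beta noise: keeps values inside (0,1) without clipping
        m = np.clip(vals, 1e-4, 1 - 1e-4)
        v = np.minimum(noise_sd**2, 0.9 * m * (1 - m))
        conc = m * (1 - m) / v - 1.0
        return rng.beta(np.maximum(m * conc, 1e-3), np.maximum((1 - m) * conc, 1e-3))
    raise ValueError(f"unknown noise model {noise_model!r}")


# ---------------------------------------------------------------------------


def _annotation(config: SimConfig, lay: dict, rng: np.random.Generator) -> ProbeAnnotation:
    n = config.n_cpgs
    per_chrom = int(np.ceil(n / 6))
    chroms = np.array([f"chr{i // per_chrom + 1}" for i in range(n)], dtype=object)
    gaps = rng.integers(300, 3001, size=n)
    gaps[lay["mediator"]] = rng.integers(150, 500, size=len(lay["mediator"]))  # DMR-like cluster
    pos = np.empty(n, dtype=np.int64)
    start = 0
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        pos[idx] = 10_000 + np.cumsum(gaps[idx])
    genes = np.array([f"GENE{i // 10:05d}" for i in range(n)], dtype=object)
    return ProbeAnnotation(pd.DataFrame({
        "cpg_id": _cpg_ids(n), "chromosome": chroms, "position": pos, "gene": genes,
    }))


def _draw_genotypes(config, lay, ann, rng, n_pool):
    """SNP table: tag SNP near the mediator cluster, one cis SNP per
    methQTL CpG, PRS SNPs and background SNPs elsewhere."""
    snp_ids, chroms, positions, mafs, roles = [], [], [], [], []
    cpg_pos = ann.table.set_index("cpg_id")

    med_ids = _cpg_ids(config.n_cpgs)[lay["mediator"]]
    if len(med_ids):
        row = cpg_pos.loc[med_ids[0]]
        snp_ids.append(HLA_TAG_SNP)
        chroms.append(row["chromosome"])
        positions.append(int(row["position"]) + 1200)
        mafs.append(config.hla_maf)
        roles.append("hla")

    qtl_ids = _cpg_ids(config.n_cpgs)[lay["methqtl"]]
    for i, cid in enumerate(qtl_ids):
        row = cpg_pos.loc[cid]
        snp_ids.append(f"rsQ{i:04d}")
        chroms.append(row["chromosome"])
        positions.append(max(1, int(row["position"]) + int(rng.integers(-15000, 15001))))
        mafs.append(float(rng.uniform(0.2, 0.5)))
        roles.append("methqtl")

    direct_qtl_ids = _cpg_ids(config.n_cpgs)[lay["direct"][: config.n_direct_qtl_cpgs]]
    for i, cid in enumerate(direct_qtl_ids):
        row = cpg_pos.loc[cid]
        snp_ids.append(f"rsD{i:04d}")
        chroms.append(row["chromosome"])
        positions.append(max(1, int(row["position"]) + int(rng.integers(-15000, 15001))))
        mafs.append(float(rng.uniform(0.2, 0.5)))
        roles.append("direct_qtl")

    for i in range(config.n_prs_snps):
        snp_ids.append(f"rsP{i:04d}")
        chroms.append(f"chr{int(rng.integers(7, 23))}")
        positions.append(int(rng.integers(1_000_000, 50_000_000)))
        mafs.append(float(rng.uniform(0.1, 0.9)))
        roles.append("prs")

    for i in range(config.n_background_snps):
        snp_ids.append(f"rsB{i:04d}")
        chroms.append(f"chr{int(rng.integers(1, 7))}")
        positions.append(int(rng.integers(10_000, 2_000_000)))
        mafs.append(float(rng.uniform(0.05, 0.5)))
        roles.append("background")

    mafs = np.asarray(mafs)
    dosages = rng.binomial(2, mafs[:, None], size=(len(snp_ids), n_pool)).astype(float)
    table = GenotypeTable(
        dosages, np.asarray(snp_ids, dtype=object),
        np.array([f"P{j:05d}" for j in range(n_pool)], dtype=object),
        np.asarray(chroms, dtype=object), np.asarray(positions, dtype=np.int64),
    )
    return table, np.asarray(roles, dtype=object), mafs


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept making mean logistic probability equal ``target``."""
    b0 = np.log(target / (1 - target)) - lp.mean()
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-(lp + b0)))
        diff = p.mean() - target
        if abs(diff) < 1e-10:
            break
        grad = np.maximum((p * (1 - p)).mean(), 1e-12)
        b0 -= diff / grad
    return float(b0)


def _methqtl_truth(config, lay, ids, genotypes, roles):
    """True (CpG, SNP, effect) triples for every genotype-driven shift."""
    cpgs, snps, effs = [], [], []
    cpgs += list(ids[lay["methqtl"]])
    snps += list(genotypes.snp_ids[np.flatnonzero(roles == "methqtl")])
    effs += [config.methqtl_effect] * len(lay["methqtl"])
    cpgs += list(ids[lay["direct"][: config.n_direct_qtl_cpgs]])
    snps += list(genotypes.snp_ids[np.flatnonzero(roles == "direct_qtl")])
    effs += [config.direct_qtl_effect] * min(config.n_direct_qtl_cpgs, len(lay["direct"]))
    if config.mediation_mode != "reverse":
        cpgs += list(ids[lay["mediator"]])
        snps += [HLA_TAG_SNP] * len(lay["mediator"])
        effs += [config.mediator_qtl_effect] * len(lay["mediator"])
    return pd.DataFrame({"cpg_id": cpgs, "snp_id": snps, "effect_per_allele": effs})


def generate_cohort(config: SimConfig) -> SimCohort:
    """Generate a full synthetic cohort with ground truth.

    A pool three times the requested size is drawn, phenotypes are sampled
    from the generating logistic model, and exactly ``n_cases`` cases and
    ``n_controls`` controls are kept, emulating case-control ascertainment.
    """
    rng = np.random.default_rng(config.seed)
    lay = _layout(config)
    ids = _cpg_ids(config.n_cpgs)
    reference = generate_reference(config, rng)
    ann = _annotation(config, lay, rng)

    n_pool = 3 * config.n_samples
    geno_pool, roles, mafs = _draw_genotypes(config, lay, ann, rng, n_pool)
    hla = geno_pool.dosage_of(HLA_TAG_SNP) if "hla" in roles else np.zeros(n_pool)

    # --- feasibility of implanted shifts (deterministic parts)
    def _infeasible(base, shift, what, cid):
        if not (0.0 <= base + shift <= 1.0):
            raise ValueError(
                f"implanted {what} effect at CpG {cid} pushes beta to "
                f"{base + shift:.3f}, outside [0,1]"
            )

    # --- mediator cluster (co-methylated; shares one latent factor)
    shared = rng.normal(0.0, config.mediator_shared_sd, size=n_pool)
    med_idio = rng.normal(0.0, config.mediator_idio_sd, size=(len(lay["mediator"]), n_pool))
    med_vals = shared[None, :] + med_idio
    if config.mediation_mode in ("chain", "independent"):
        for cid in ids[lay["mediator"]]:
            _infeasible(config.mediator_baseline, 2 * config.mediator_qtl_effect,
                        "mediator methQTL", cid)
        med_vals = med_vals + config.mediator_qtl_effect * hla[None, :]
    mediator_beta_pool = config.mediator_baseline + med_vals  # before any reverse shift

    # --- whole-blood direct (environmental) effects
    direct_bio = rng.normal(0.0, config.direct_bio_sd, size=(len(lay["direct"]), n_pool))
    for cid in ids[lay["direct"]]:
        _infeasible(config.direct_baseline, config.direct_effect_delta, "whole-blood", cid)

    # --- cis methQTL shifts
    qtl_rows = np.flatnonzero(roles == "methqtl")
    for cid in ids[lay["methqtl"]]:
        _infeasible(config.methqtl_baseline, 2 * config.methqtl_effect, "methQTL", cid)
    qtl_shift = config.methqtl_effect * geno_pool.dosages[qtl_rows]  # aligned to lay["methqtl"]

    # --- polygenic score (true weights)
    prs_rows = np.flatnonzero(roles == "prs")
    raw = rng.lognormal(mean=np.log(0.05), sigma=0.5, size=len(prs_rows))
    w = np.clip(raw, 0.0, config.prs_max_abs_logor) * rng.choice([-1.0, 1.0], size=len(prs_rows))
    prs_pool = w @ (geno_pool.dosages[prs_rows] - (2 * mafs[prs_rows])[:, None])

    # --- phenotype-generating linear predictor
    log_or = np.log(config.risk_haplotype_or)
    gamma_med = (log_or / (config.n_mediator_cpgs * config.mediator_qtl_effect)
                 if config.n_mediator_cpgs else 0.0)
    if config.mediation_mode == "chain":
        # haplotype acts on phenotype only through the mediator CpGs
        lp = gamma_med * (mediator_beta_pool - config.mediator_baseline).sum(axis=0)
    else:
        lp = log_or * hla
    lp = lp + prs_pool
    lp = lp - lp.mean()
    target_prev = config.n_cases / config.n_samples
    b0 = _solve_intercept(lp, max(0.25, min(0.5, target_prev)))
    prob = 1.0 / (1.0 + np.exp(-(lp + b0)))
    pheno_pool = (rng.random(n_pool) < prob).astype(int)

    case_idx = np.flatnonzero(pheno_pool == 1)
    ctrl_idx = np.flatnonzero(pheno_pool == 0)
    if len(case_idx) < config.n_cases or len(ctrl_idx) < config.n_controls:
        raise ValueError("simulation pool too small for requested case/control counts")
    keep = np.concatenate([case_idx[: config.n_cases], ctrl_idx[: config.n_controls]])
    keep = rng.permutation(keep)
    pheno = pheno_pool[keep]
    n = len(keep)

    # --- reverse mode: phenotype shifts the mediator CpGs directly
    mediator_beta = mediator_beta_pool[:, keep]
    if config.mediation_mode == "reverse":
        mediator_beta = mediator_beta + config.reverse_shift * pheno[None, :]

    # --- per-sample cell fractions from group-specific Dirichlet
    K = len(config.cell_types)
    fr = np.empty((n, K))
    for g, means in ((0, config.fraction_means_control), (1, config.fraction_means_case)):
        rows = np.flatnonzero(pheno == g)
        alpha = config.dirichlet_concentration * np.array(
            [means[c] for c in config.cell_types])
        fr[rows] = rng.dirichlet(alpha, size=len(rows))

    # --- mix profiles (cell-specific case effects applied within the
    # designated cell type's profile; by linearity of mixing this equals
    # an additive shift of delta_beta * f_k for case samples)
    vals = reference.values @ fr.T

    cell_eff_rows = []
    eff_idx = lay["cell_effect"]
    assign = [ct for ct in config.cell_types for _ in range(config.cell_effect_counts.get(ct, 0))]
    half = len(eff_idx) // 2 + len(eff_idx) % 2
    for j, (row, ct) in enumerate(zip(eff_idx, assign)):
        delta = config.cell_effect_delta if j < half else -config.cell_effect_delta
        base = reference.values[row, list(config.cell_types).index(ct)]
        _infeasible(base, delta, f"cell-specific ({ct})", ids[row])
        k = list(config.cell_types).index(ct)
        vals[row] += delta * fr[:, k] * pheno
        cell_eff_rows.append((ids[row], ct, delta, "case"))

    vals[lay["direct"]] += direct_bio[:, keep] + config.direct_effect_delta * pheno[None, :]
    vals[lay["methqtl"]] += qtl_shift[:, keep]
    dqtl_rows = np.flatnonzero(roles == "direct_qtl")
    if len(dqtl_rows):
        for cid in ids[lay["direct"][: config.n_direct_qtl_cpgs]]:
            _infeasible(config.direct_baseline + config.direct_effect_delta,
                        2 * config.direct_qtl_effect, "direct-CpG methQTL", cid)
        vals[lay["direct"][: config.n_direct_qtl_cpgs]] += (
            config.direct_qtl_effect * geno_pool.dosages[dqtl_rows][:, keep])
    vals[lay["mediator"]] = mediator_beta

    if config.noise_sd > 0:
        vals = _add_noise(vals, config.noise_sd, rng, config.noise_model)
    vals = np.clip(vals, 0.0, 1.0)

    sample_ids = np.array([f"S{j:05d}" for j in range(n)], dtype=object)
    beta = BetaMatrix(vals, ids.copy(), sample_ids)
    genotypes = GenotypeTable(
        geno_pool.dosages[:, keep], geno_pool.snp_ids, sample_ids,
        geno_pool.chromosome, geno_pool.position,
    )
    meta = SampleMeta(pd.DataFrame({
        "sample_id": sample_ids,
        "phenotype": pheno,
        "age": rng.integers(18, 60, size=n),
        "sex": rng.choice(["F", "M"], size=n, p=[0.7, 0.3]),
        "region": rng.choice(["north", "central", "south"], size=n),
        "batch": rng.choice(["b1", "b2"], size=n),
    }))

    truth = SimTruth(
        cell_effects=pd.DataFrame(
            cell_eff_rows, columns=["cpg_id", "cell_type", "delta_beta", "affected_group"]),
        direct_effects=pd.DataFrame({
            "cpg_id": ids[lay["direct"]],
            "delta_beta": config.direct_effect_delta,
        }),
        methqtl=_methqtl_truth(config, lay, ids, genotypes, roles),
        mediator_cpgs=list(ids[lay["mediator"]]),
        mediation_mode=config.mediation_mode,
        true_fractions=pd.DataFrame(fr, index=sample_ids, columns=list(config.cell_types)),
        prs_weights=pd.Series(w, index=genotypes.snp_ids[prs_rows], name="log_or"),
        phenotype_coefficients={
            "intercept": b0, "gamma_mediator": gamma_med,
            "log_or_haplotype": log_or, "mode": config.mediation_mode,
        },
    )
    sig_ids = ids[lay["signature"]]
    return SimCohort(beta, genotypes, meta, ann, reference, sig_ids, truth, config)
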