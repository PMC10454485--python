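"""Per-CpG epigenome-wide association models.

The whole-blood model is a logistic regression of case/control status on
each CpG's beta value plus age, sex, cell fractions (one type dropped to
break the sum-to-one collinearity) and region:

    phenotype ~ CpG_i + age + sex + cell fractions + region

The genotype-risk-corrected variant adds the risk-haplotype dosage and a
polygenic risk score as covariates; CpGs whose whole-blood association is
genotype-driven lose significance there. Effect size is the case-control
difference in mean beta (delta-beta). Regions of correlated CpGs are
summarized with Fisher's and Stouffer's p-value combinations and the
harmonic mean of BH-adjusted member p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._lm import logit, ols, drop_collinear
from .datamodel import BetaMatrix, ProbeAnnotation, SampleMeta, delta_beta
from .deconvolution import CellFractions

__all__ = [
    "DMPResult", "DMRResult", "build_design", "fit_dmp", "run_ewas",
    "run_grc_ewas", "sensitivity_scan", "combine_dmr", "expr_meth_correlation",
    "GENOME_WIDE_P", "DELTA_BETA_CUT",
]

GENOME_WIDE_P = 9.8e-8   # genome-wide significance threshold for EWAS
DELTA_BETA_CUT = 0.02    # large-effect flag on |delta beta|
DEFAULT_DROPPED_CELL = "Neu"  # neutrophils: largest fraction, dropped for identifiability


@dataclass
class DMPResult:
    cpg_id: str
    coefficient: float
    p: float
    delta_beta: float
    significant: bool
    large_effect: bool
    estimable: bool = True
    note: str = ""


@dataclass
class DMRResult:
    chromosome: str
    start: int
    end: int
    cpg_ids: list
    fisher_p: float
    stouffer_p: float
    harmonic_mean_fdr: float
    significant: bool
    clipped: bool = False


def build_design(
    meta: SampleMeta,
    fractions: CellFractions | None = None,
    drop_cell: str = DEFAULT_DROPPED_CELL,
    extra: dict | None = None,
    include_batch: bool = False,
) -> tuple[np.ndarray, list]:
    """Covariate design matrix (without the CpG column).

    Categorical covariates are dummy-coded with the first level as the
    reference; one cell fraction is dropped against the intercept.
    """
    t = meta.table
    cols = [np.ones(len(t))]
    names = ["intercept"]
    cols.append(t["age"].to_numpy(dtype=float))
    names.append("age")
    for cat in ["sex", "region"] + (["batch"] if include_batch and "batch" in t else []):
        levels = sorted(pd.unique(t[cat].astype(str)))
        for lev in levels[1:]:
            cols.append((t[cat].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{cat}[{lev}]")
    if fractions is not None:
        fr = fractions.table.loc[list(meta.sample_ids)]
        for ct in fr.columns:
            if ct == drop_cell:
                continue
            cols.append(fr[ct].to_numpy(dtype=float))
            names.append(f"frac_{ct}")
    for name, vec in (extra or {}).items():
        cols.append(np.asarray(vec, dtype=float))
        names.append(name)
    X = np.column_stack(cols)
    kept, dropped = drop_collinear(X)
    if dropped:
        warnings.warn(
            f"collinear covariates dropped from EWAS design: {[names[j] for j in dropped]}"
        )
        X = X[:, kept]
        names = [names[j] for j in kept]
    return X, names


def _fit_one(beta_i, X_cov, pheno, p_threshold, delta_beta_cut, cpg_id, db):
    """Logistic fit of phenotype on one CpG plus covariates."""
    if np.nanstd(beta_i) == 0:
        return DMPResult(cpg_id, np.nan, np.nan, db, False, False,
                         estimable=False, note="constant beta")
    X = np.column_stack([X_cov, beta_i])
    fit = logit(X, pheno, check_rank=False)
    coef, p = fit.params[-1], fit.pvalues[-1]
    if fit.separated or not np.isfinite(p):
        return DMPResult(cpg_id, np.nan, np.nan, db, False, False,
                         estimable=False, note="separation or non-convergence")
    return DMPResult(
        cpg_id, float(coef), float(p), float(db),
        significant=bool(p < p_threshold),
        large_effect=bool(abs(db) > delta_beta_cut),
    )


def fit_dmp(
    beta_i: np.ndarray,
    meta: SampleMeta,
    fractions: CellFractions | None = None,
    cpg_id: str = "cpg",
    p_threshold: float = GENOME_WIDE_P,
    delta_beta_cut: float = DELTA_BETA_CUT,
    extra: dict | None = None,
) -> DMPResult:
    """Single-CpG case/control logistic model with a Wald test on the CpG."""
    beta_i = np.asarray(beta_i, dtype=float)
    pheno = meta.phenotype
    if not (pheno == 1).any() or not (pheno == 0).any():
        raise ValueError("need at least one case and one control")
    if not np.isfinite(beta_i).all():
        raise ValueError("beta values must be finite (filter or impute first)")
    X_cov, _ = build_design(meta, fractions, extra=extra)
    case, ctrl = pheno == 1, pheno == 0
    db = float(beta_i[case].mean() - beta_i[ctrl].mean())
    return _fit_one(beta_i, X_cov, pheno, p_threshold, delta_beta_cut, cpg_id, db)


def run_ewas(
    beta: BetaMatrix,
    meta: SampleMeta,
    fractions: CellFractions | None = None,
    p_threshold: float = GENOME_WIDE_P,
    delta_beta_cut: float = DELTA_BETA_CUT,
    extra: dict | None = None,
) -> pd.DataFrame:
    """Scan every CpG; a failing CpG is reported, never aborts the scan.

    Returns one row per CpG with coefficient, Wald p, delta-beta and the
    significance/large-effect flags; summary counts are in ``.attrs``.
    """
    pheno = meta.phenotype
    if not (pheno == 1).any() or not (pheno == 0).any():
        raise ValueError("need at least one case and one control")
    X_cov, _ = build_design(meta, fractions, extra=extra)
    db_all = delta_beta(beta, pheno)
    rows = []
    for i, cpg in enumerate(beta.cpg_ids):
        b = beta.values[i]
        if not np.isfinite(b).all():
            rows.append(DMPResult(cpg, np.nan, np.nan, np.nan, False, False,
                                  estimable=False, note="missing beta"))
            continue
        rows.append(_fit_one(b, X_cov, pheno, p_threshold, delta_beta_cut,
                             cpg, db_all.iloc[i]))
    out = pd.DataFrame([r.__dict__ for r in rows])
    out.attrs["n_significant"] = int(out["significant"].sum())
    out.attrs["n_large_effect"] = int((out["significant"] & out["large_effect"]).sum())
    out.attrs["p_threshold"] = p_threshold
    out.attrs["delta_beta_cut"] = delta_beta_cut
    return out


def run_grc_ewas(
    beta: BetaMatrix,
    meta: SampleMeta,
    fractions: CellFractions | None,
    hla_dosage: np.ndarray,
    prs_score: np.ndarray,
    p_threshold: float = GENOME_WIDE_P,
    delta_beta_cut: float = DELTA_BETA_CUT,
) -> pd.DataFrame:
    """EWAS additionally adjusted for known genetic risk (haplotype + PRS)."""
    hla_dosage = np.asarray(hla_dosage, dtype=float)
    prs_score = np.asarray(prs_score, dtype=float)
    if len(hla_dosage) != beta.n_samples or len(prs_score) != beta.n_samples:
        raise ValueError("haplotype dosage and PRS must align with the samples")
    return run_ewas(beta, meta, fractions, p_threshold, delta_beta_cut,
                    extra={"hla": hla_dosage, "prs": prs_score})


def sensitivity_scan(beta: BetaMatrix, covariate: np.ndarray) -> pd.DataFrame:
    """Per-CpG influence of one covariate on beta.

    Numeric covariates: simple linear regression with a slope t-test.
    Categorical covariates: one-way ANOVA. R-squared (variance explained)
    is reported either way.
    """
    cov = np.asarray(covariate)
    if len(cov) != beta.n_samples:
        raise ValueError("covariate must align with the samples")
    numeric = np.issubdtype(cov.dtype, np.number)
    rows = []
    if numeric:
        x = cov.astype(float)
        if np.std(x) == 0:
            raise ValueError("covariate has a single value; nothing to test")
        for i, cpg in enumerate(beta.cpg_ids):
            res = stats.linregress(x, beta.values[i])
            rows.append({"cpg_id": cpg, "statistic": res.slope / res.stderr
                         if res.stderr > 0 else np.nan,
                         "p": res.pvalue, "variance_explained": res.rvalue ** 2})
    else:
        levels = pd.unique(cov)
        if len(levels) < 2:
            raise ValueError("categorical covariate needs at least two levels")
        groups_idx = [np.flatnonzero(cov == lev) for lev in levels]
        for i, cpg in enumerate(beta.cpg_ids):
            groups = [beta.values[i][g] for g in groups_idx]
            F, p = stats.f_oneway(*groups)
            grand = beta.values[i].mean()
            ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ss_total = ((beta.values[i] - grand) ** 2).sum()
            r2 = ss_between / ss_total if ss_total > 0 else np.nan
            rows.append({"cpg_id": cpg, "statistic": F, "p": p,
                         "variance_explained": r2})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DMR combination


def _regions(ann: pd.DataFrame, max_gap: int, min_cpgs: int):
    for chrom, sub in ann.groupby("chromosome", sort=True):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        start = 0
        for b in list(breaks) + [len(pos) - 1]:
            block = sub.iloc[start:b + 1]
            if len(block) >= min_cpgs:
                yield chrom, block
            start = b + 1


def combine_dmr(
    dmps: pd.DataFrame,
    annotation: ProbeAnnotation,
    max_gap: int = 1000,
    min_cpgs: int = 3,
    alpha: float = 0.05,
) -> list:
    """Combine per-CpG p-values over positional runs of CpGs.

    Candidate regions are maximal runs of tested CpGs on one chromosome
    with inter-CpG gaps <= ``max_gap`` (1-based, closed coordinates) and at
    least ``min_cpgs`` members. A region is significant when all three of
    Fisher's combination, Stouffer's Z and the harmonic mean of BH-adjusted
    member p-values are <= ``alpha``.
    """
    dmps = dmps.dropna(subset=["p"])
    pmap = dmps.set_index("cpg_id")["p"]
    tiny = 1e-300  # smallest p whose reciprocal is still representable
    clipped_any = (pmap <= tiny).any()
    pmap = pmap.clip(lower=tiny)
    bh = pd.Series(
        multipletests(pmap.to_numpy(), method="fdr_bh")[1], index=pmap.index
    ).clip(lower=tiny)
    ann = annotation.table[annotation.table["cpg_id"].isin(pmap.index)]
    results = []
    for chrom, block in _regions(ann, max_gap, min_cpgs):
        ids = block["cpg_id"].tolist()
        p = pmap.loc[ids].to_numpy()
        k = len(p)
        fisher_x2 = -2.0 * np.log(p).sum()
        fisher_p = float(stats.chi2.sf(fisher_x2, df=2 * k))
        z = stats.norm.isf(p)  # one-sided z transform
        stouffer_p = float(stats.norm.sf(z.sum() / np.sqrt(k)))
        hm = float(k / (1.0 / bh.loc[ids].to_numpy()).sum())
        results.append(DMRResult(
            chromosome=str(chrom),
            start=int(block["position"].min()),
            end=int(block["position"].max()),
            cpg_ids=ids,
            fisher_p=fisher_p,
            stouffer_p=stouffer_p,
            harmonic_mean_fdr=hm,
            significant=bool(fisher_p <= alpha and stouffer_p <= alpha and hm <= alpha),
            clipped=bool(clipped_any and (pmap.loc[ids] <= tiny).any()),
        ))
    return results


def dmr_to_bed(dmrs: list) -> pd.DataFrame:
    """DMRs as BED records (0-based half-open, converted from 1-based closed)."""
    return pd.DataFrame({
        "chrom": [d.chromosome for d in dmrs],
        "chromStart": [d.start - 1 for d in dmrs],
        "chromEnd": [d.end for d in dmrs],
        "name": [f"DMR_{i}" for i in range(len(dmrs))],
        "score": [min(1000, int(-10 * np.log10(max(d.fisher_p, 1e-100)))) for d in dmrs],
    })


def expr_meth_correlation(expression: np.ndarray, beta_block: BetaMatrix) -> pd.DataFrame:
    """Pearson correlation of one gene's expression with each CpG's beta."""
    expr = np.asarray(expression, dtype=float)
    if len(expr) != beta_block.n_samples:
        raise ValueError("expression must align with the samples")
    if len(expr) < 3:
        raise ValueError("need at least 3 paired samples")
    if np.std(expr) == 0:
        raise ValueError("expression has zero variance; correlation undefined")
    rows = []
    for i, cpg in enumerate(beta_block.cpg_ids):
        b = beta_block.values[i]
        if np.std(b) == 0:
            raise ValueError(f"beta at CpG {cpg!r} has zero variance; correlation undefined")
        r, p = stats.pearsonr(expr, b)
        rows.append({"cpg_id": cpg, "r": r, "p": p})
    return pd.DataFrame(rows)
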