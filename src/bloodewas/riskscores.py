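"""Methylation and genetic risk scores with ROC comparison.

The genotype-risk-corrected methylation score of a sample is

    grcMethScore_s = sum_i beta_si * dbeta_i

over the CpGs that stay significant after adjusting the EWAS for known
genetic risk, weighted by their delta-beta from that adjusted scan. It is
compared against a polygenic risk score (weighted allele-dosage sum) and
the risk-haplotype tag-SNP dosage via logistic models and ROC AUC (the
Mann-Whitney pair statistic with ties counted one half), with DeLong or
bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._lm import logit
from .datamodel import BetaMatrix, GenotypeTable

__all__ = [
    "ROCResult", "grc_meth_score", "prs_score", "hla_score",
    "combine_scores", "roc_auc", "correlate_scores",
]


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    ci_method: str = "delong"


def grc_meth_score(beta: BetaMatrix, weights: pd.Series) -> pd.Series:
    """Weighted beta sum over the selected DMPs (weights = delta-beta)."""
    weights = pd.Series(weights).astype(float)
    if not np.isfinite(weights.to_numpy()).all():
        raise ValueError("score weights must be finite")
    missing = set(weights.index) - set(beta.cpg_ids)
    if missing:
        raise ValueError(f"weighted CpGs absent from beta matrix: {sorted(missing)[:5]}")
    idx = pd.Index(beta.cpg_ids).get_indexer(weights.index)
    block = beta.values[idx]
    if not np.isfinite(block).all():
        raise ValueError("missing beta at a weighted CpG; no silent imputation")
    return pd.Series(weights.to_numpy() @ block, index=beta.sample_ids,
                     name="grc_meth_score")


def prs_score(genotypes: GenotypeTable, effects: pd.Series) -> pd.Series:
    """Polygenic risk score: sum of dosage x effect weight over SNPs."""
    effects = pd.Series(effects).astype(float)
    missing = sorted(set(effects.index) - set(genotypes.snp_ids))
    if missing:
        raise ValueError(f"effect SNPs absent from genotype table: {missing[:5]}")
    idx = pd.Index(genotypes.snp_ids).get_indexer(effects.index)
    block = genotypes.dosages[idx]
    if not np.isfinite(block).all():
        raise ValueError("missing dosage at a scored SNP; handle missingness first")
    return pd.Series(effects.to_numpy() @ block, index=genotypes.sample_ids, name="prs")


def hla_score(genotypes: GenotypeTable, tag_snp: str) -> pd.Series:
    """Risk-haplotype score: the tag SNP's risk-allele dosage (0/1/2).

    Samples with a missing call are returned as NaN (flagged-missing, not
    zero) and must be excluded from score comparisons by the caller.
    """
    d = genotypes.dosage_of(tag_snp)
    return pd.Series(d, index=genotypes.sample_ids, name="hla_score")


def combine_scores(predictors: pd.DataFrame, phenotype: np.ndarray) -> dict:
    """Logistic fit of phenotype on one or more per-sample scores.

    Returns fitted probabilities (for ROC), coefficients, and flags for
    separation or dropped collinear predictors.
    """
    X = np.column_stack([np.ones(len(predictors)),
                         predictors.to_numpy(dtype=float)])
    names = ["intercept"] + list(predictors.columns)
    y = np.asarray(phenotype, dtype=float)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("both classes must be present")
    fit = logit(X, y, check_rank=True)
    eta = np.nansum(np.nan_to_num(fit.params) * X, axis=1)
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    return {
        "probabilities": pd.Series(prob, index=predictors.index, name="p_case"),
        "coefficients": pd.Series(fit.params, index=names),
        "bse": pd.Series(fit.bse, index=names),
        "pvalues": pd.Series(fit.pvalues, index=names),
        "separated": fit.separated,
        "dropped": [names[j] for j in fit.dropped],
    }


def _auc_mann_whitney(cases: np.ndarray, controls: np.ndarray) -> float:
    """AUC as the tie-aware Mann-Whitney pair statistic."""
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    n1, n0 = len(cases), len(controls)
    return (ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _delong_ci(cases, controls, auc, alpha=0.05):
    """DeLong variance via midrank structural components."""
    n1, n0 = len(cases), len(controls)
    all_s = np.concatenate([cases, controls])
    mid = stats.rankdata(all_s)
    mid_case = stats.rankdata(cases)
    mid_ctrl = stats.rankdata(controls)
    v10 = (mid[:n1] - mid_case) / n0          # per-case components
    v01 = 1.0 - (mid[n1:] - mid_ctrl) / n1    # per-control components
    var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0
    z = stats.norm.isf(alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def roc_auc(
    scores: np.ndarray,
    phenotype: np.ndarray,
    ci_method: str = "delong",
    n_bootstrap: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ROCResult:
    """AUC with a confidence interval (DeLong default, bootstrap optional)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(phenotype)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("both classes must be present")
    cases, controls = s[y == 1], s[y == 0]
    auc = _auc_mann_whitney(cases, controls)
    if ci_method == "delong":
        lo, hi = _delong_ci(cases, controls, auc, alpha)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            reps[b] = _auc_mann_whitney(
                rng.choice(cases, len(cases)), rng.choice(controls, len(controls)))
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ROCResult(float(auc), float(lo), float(hi),
                     int(len(cases)), int(len(controls)), ci_method)


def roc_points(scores: np.ndarray, phenotype: np.ndarray) -> pd.DataFrame:
    """FPR/TPR pairs over all score thresholds (for plotting or export)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(phenotype)
    order = np.argsort(-s, kind="mergesort")
    tp = np.cumsum(y[order] == 1)
    fp = np.cumsum(y[order] == 0)
    return pd.DataFrame({
        "fpr": np.concatenate([[0], fp / max(1, (y == 0).sum())]),
        "tpr": np.concatenate([[0], tp / max(1, (y == 1).sum())]),
    })


def correlate_scores(score_a: np.ndarray, score_b: np.ndarray, alpha: float = 0.05) -> dict:
    """Pearson R between two scores with Fisher-z CI and t-based p."""
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if len(a) != len(b) or len(a) < 4:
        raise ValueError("need at least 4 aligned samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance score; correlation undefined")
    r, p = stats.pearsonr(a, b)
    n = len(a)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.isf(alpha / 2) / np.sqrt(n - 3)
    return {"r": float(r), "p": float(p),
            "ci_low": float(np.tanh(z - half)), "ci_high": float(np.tanh(z + half))}
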