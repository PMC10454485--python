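"""Per-cell-type attribution of differential methylation.

For each cell type k, an ordinary least-squares model of the CpG's
M value on the estimated cell fraction and its interaction with
phenotype:

    M_i ~ f_k + f_k : phenotype + age + sex

The interaction coefficient measures how strongly the case/control
methylation difference scales with the abundance of that cell type; a
CpG is a cell-type-specific DMP (csDMP) for type k when |estimate| > 2
(M-value units per fraction) and the interaction p-value is below the
genome-wide threshold 9.8e-8. Fitting one small model per cell type
avoids the overburdened joint interaction model with all cell types at
once; the joint model is kept only as a small-scale test oracle.
M values (not beta) are the response, which avoids the
fraction-dependent bias of beta-scale interaction fits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._lm import ols
from .datamodel import MValueMatrix, SampleMeta
from .deconvolution import CellFractions
from .ewas import GENOME_WIDE_P

__all__ = ["CsDMPResult", "fit_csdmp", "run_csdmp_scan", "classify_csdmp",
           "summarize_csdmp", "ESTIMATE_CUT"]

ESTIMATE_CUT = 2.0  # |interaction estimate| cut, M-value units per (fraction x phenotype)


@dataclass
class CsDMPResult:
    cpg_id: str
    cell_type: str
    interaction_estimate: float
    p: float
    direction: str = ""          # "hyper" | "hypo"
    significant: bool = False
    estimable: bool = True
    note: str = ""


def _covariate_block(meta: SampleMeta) -> np.ndarray:
    """age + sex dummies (no intercept column; added by caller)."""
    t = meta.table
    cols = [t["age"].to_numpy(dtype=float)]
    levels = sorted(pd.unique(t["sex"].astype(str)))
    for lev in levels[1:]:
        cols.append((t["sex"].astype(str) == lev).to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_csdmp(
    m_i: np.ndarray,
    cell_type: str,
    fractions: CellFractions,
    meta: SampleMeta,
) -> CsDMPResult:
    """Fit the per-cell-type interaction model at one CpG."""
    m_i = np.asarray(m_i, dtype=float)
    if cell_type not in fractions.cell_types:
        raise ValueError(f"unknown cell type {cell_type!r}")
    pheno = meta.phenotype
    if not (pheno == 1).any() or not (pheno == 0).any():
        raise ValueError("need at least one case and one control")
    f = fractions.table.loc[list(meta.sample_ids), cell_type].to_numpy(dtype=float)
    if np.std(f) == 0:
        raise ValueError(f"cell fraction for {cell_type!r} has zero variance")
    X = np.column_stack([
        np.ones(len(f)), f, f * pheno, _covariate_block(meta),
    ])
    fit = ols(X, m_i, check_rank=True)
    est, p = fit.params[2], fit.pvalues[2]
    if 2 in fit.dropped or not np.isfinite(est):
        return CsDMPResult("cpg", cell_type, np.nan, np.nan,
                           estimable=False, note="rank-deficient design")
    res = CsDMPResult("cpg", cell_type, float(est), float(p))
    return classify_csdmp(res)


def run_csdmp_scan(
    m: MValueMatrix,
    fractions: CellFractions,
    meta: SampleMeta,
    cell_types: list | None = None,
    estimate_cut: float = ESTIMATE_CUT,
    p_cut: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Fit the interaction model for every (CpG, cell type) pair."""
    cell_types = cell_types or fractions.cell_types
    pheno = meta.phenotype
    cov = _covariate_block(meta)
    rows = []
    frt = fractions.table.loc[list(meta.sample_ids)]
    for ct in cell_types:
        f = frt[ct].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(f)), f, f * pheno, cov])
        for i, cpg in enumerate(m.cpg_ids):
            fit = ols(X, m.values[i], check_rank=False)
            res = classify_csdmp(
                CsDMPResult(cpg, ct, float(fit.params[2]), float(fit.pvalues[2])),
                estimate_cut, p_cut)
            rows.append(res)
    return pd.DataFrame([r.__dict__ for r in rows])


def classify_csdmp(
    result: CsDMPResult,
    estimate_cut: float = ESTIMATE_CUT,
    p_cut: float = GENOME_WIDE_P,
) -> CsDMPResult:
    """Apply the magnitude-and-significance rule; pure and idempotent."""
    est, p = result.interaction_estimate, result.p
    if not np.isfinite(est) or not np.isfinite(p):
        return replace(result, significant=False, direction="", estimable=False)
    return replace(
        result,
        direction="hyper" if est > 0 else "hypo",
        significant=bool(abs(est) > estimate_cut and p < p_cut),
    )


def summarize_csdmp(results: pd.DataFrame, compare: list | None = None) -> dict:
    """Bookkeeping over the significant csDMP sets.

    Returns per-cell-type totals with hyper/hypo breakdowns, and for the
    chosen comparison cell types (default: all) the unique and shared CpG
    sets, where "shared with same directionality" requires a matching
    direction in every compared cell type.
    """
    sig = results[results["significant"]]
    counts = {}
    for ct, sub in results.groupby("cell_type"):
        s = sub[sub["significant"]]
        counts[ct] = {
            "n_csdmp": int(len(s)),
            "n_hyper": int((s["direction"] == "hyper").sum()),
            "n_hypo": int((s["direction"] == "hypo").sum()),
        }
    compare = compare or sorted(results["cell_type"].unique())
    sets = {ct: set(sig[sig["cell_type"] == ct]["cpg_id"]) for ct in compare}
    union_others = {
        ct: set().union(*[s for o, s in sets.items() if o != ct]) if len(sets) > 1 else set()
        for ct in compare
    }
    unique = {ct: sorted(sets[ct] - union_others[ct]) for ct in compare}
    shared = set.intersection(*sets.values()) if sets else set()
    dirmap = sig.set_index(["cpg_id", "cell_type"])["direction"]
    shared_same_dir = sorted(
        c for c in shared
        if len({dirmap.loc[(c, ct)] for ct in compare}) == 1
    )
    return {
        "per_cell_type": counts,
        "compared": list(compare),
        "unique": unique,
        "shared": sorted(shared),
        "shared_same_direction": shared_same_dir,
    }
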