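"""Reference-based immune-cell deconvolution of whole-blood methylation.

Each sample's beta profile over a set of cell-type signature CpGs is
modelled as a non-negative, unit-sum combination of sorted-cell reference
profiles. The estimator is non-negative least squares (Lawson-Hanson
active set) with the unit-sum constraint imposed as a strongly weighted
equation, followed by an exact renormalization of the residual slack —
a deterministic solution of the constrained projection that a general
quadratic-programming solver reproduces (the QP is kept as the
independent oracle in tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import BetaMatrix

__all__ = ["CellFractions", "estimate_fractions", "compare_fractions"]


@dataclass
class CellFractions:
    """Per-sample cell-type proportions; non-negative rows summing to 1."""

    table: pd.DataFrame  # index sample_id, columns cell types

    def __post_init__(self):
        vals = self.table.to_numpy(dtype=float)
        if (vals < -1e-12).any():
            raise ValueError("cell fractions must be non-negative")
        if np.abs(vals.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("cell fraction rows must sum to 1")

    @property
    def cell_types(self) -> list:
        return list(self.table.columns)

    def values_for(self, sample_ids) -> np.ndarray:
        return self.table.loc[list(sample_ids)].to_numpy(dtype=float)


def estimate_fractions(
    beta: BetaMatrix,
    reference: BetaMatrix,
    intercept: bool = False,
) -> CellFractions:
    """Estimate cell-type fractions for every sample.

    The fit is restricted to the reference's CpGs (which must all be
    present in ``beta``). With ``intercept=True`` a free offset absorbs any
    global shift between sample and reference scales.
    """
    if reference.n_samples < 2:
        raise ValueError("need at least 2 cell types in the reference")
    missing = set(reference.cpg_ids) - set(beta.cpg_ids)
    if missing:
        raise ValueError(f"reference CpGs absent from beta matrix: {sorted(missing)[:5]}")
    order = pd.Index(beta.cpg_ids).get_indexer(reference.cpg_ids)
    Y = beta.values[order]            # (n_ref_cpgs, n_samples)
    X = reference.values              # (n_ref_cpgs, K)
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] < 1e-10 * s[0]:
        raise ValueError("reference profiles are collinear; cannot deconvolve")
    if intercept:
        # sign-free offset under NNLS: split it into +/- parts
        one = np.ones((X.shape[0], 1))
        X = np.column_stack([one, -one, X])
    # unit-sum constraint as a heavily weighted equation (fractions only)
    lam = 100.0 * np.abs(X).max()
    sum_row = np.ones(X.shape[1]) * lam
    if intercept:
        sum_row[:2] = 0.0
    A = np.vstack([X, sum_row])
    coef = np.empty((X.shape[1], Y.shape[1]))
    for j in range(Y.shape[1]):
        coef[:, j], _ = optimize.nnls(A, np.append(Y[:, j], lam))
    if intercept:
        coef = coef[2:]
    totals = coef.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("all-zero fraction estimate; reference does not fit the data")
    fr = (coef / totals).T
    return CellFractions(pd.DataFrame(fr, index=beta.sample_ids,
                                      columns=reference.sample_ids))


def compare_fractions(
    fractions: CellFractions,
    phenotype: np.ndarray,
    test: str = "welch",
) -> pd.DataFrame:
    """Two-sided case/control comparison of each cell type's fractions.

    Returns a table with mean_case, mean_control, difference and p per
    cell type (Welch's t by default, Wilcoxon rank-sum selectable). A
    zero-variance cell type gets p = NaN and a flag.
    """
    phenotype = np.asarray(phenotype)
    vals = fractions.table.to_numpy(dtype=float)
    case = phenotype == 1
    ctrl = phenotype == 0
    if not case.any() or not ctrl.any():
        raise ValueError("both groups must be non-empty")
    rows = []
    for j, ct in enumerate(fractions.cell_types):
        a, b = vals[case, j], vals[ctrl, j]
        degenerate = a.std() < 1e-12 and b.std() < 1e-12
        if degenerate:
            p = np.nan
        elif test == "welch":
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        elif test == "wilcoxon":
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({
            "cell_type": ct, "mean_case": a.mean(), "mean_control": b.mean(),
            "difference": a.mean() - b.mean(), "p": p, "degenerate": degenerate,
        })
    return pd.DataFrame(rows)
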