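"""Causal inference test (CIT) for genotype -> methylation -> disease.

Given a genetic locus L (risk-allele dosage), a candidate mediator G
(methylation beta at a CpG) and a binary trait T, the CIT supports the
causal chain L -> G -> T when all four component conditions hold:

1. L is associated with T                      (logistic T ~ L)
2. L is associated with G given T              (linear   L ~ G + T)
3. G is associated with T given L              (logistic T ~ G + L)
4. L is independent of T given G               (permutation equivalence test)

Condition 4 is the discriminating one: it separates full mediation from
a direct L -> T effect. It is tested by comparing the observed Wald
chi-square of L in T ~ G + L against its distribution over surrogate
mediators G* that preserve the G ~ L relationship but carry no
information about T beyond L (G* = fitted(G ~ L) + permuted residuals).
Under mediation the observed statistic falls in the lower tail of that
distribution; the component p-value is the fraction of permuted
statistics at or below the observed one. The omnibus p-value is the
maximum of the four components, so every link of the chain must hold.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats

from ._lm import logit, ols

__all__ = ["CITResult", "cit_test", "select_risk_haplotype"]


@dataclass
class CITResult:
    p_assoc_LT: float
    p_assoc_LG_given_T: float
    p_assoc_GT_given_L: float
    p_indep_LT_given_G: float
    n_permutations: int
    seed: int

    @property
    def omnibus_p(self) -> float:
        return float(max(self.p_assoc_LT, self.p_assoc_LG_given_T,
                         self.p_assoc_GT_given_L, self.p_indep_LT_given_G))


def _wald_chi2_last(X, y):
    fit = logit(X, y, check_rank=False)
    z = fit.stat[-1]
    return float(z * z) if np.isfinite(z) else np.inf


def cit_test(
    L: np.ndarray,
    G: np.ndarray,
    T: np.ndarray,
    n_permutations: int = 500,
    seed: int = 0,
) -> CITResult:
    """Run the four-component causal inference test.

    L: genotype dosage per sample; G: mediator methylation per sample;
    T: binary trait. Binary T is handled with logistic components and the
    continuous mediator with linear ones. Deterministic given ``seed``.
    """
    L = np.asarray(L, dtype=float)
    G = np.asarray(G, dtype=float)
    T = np.asarray(T, dtype=float)
    if not (len(L) == len(G) == len(T)):
        raise ValueError("L, G, T must be aligned")
    if np.std(L) == 0:
        raise ValueError("L is constant; CIT undefined")
    if np.std(G) == 0:
        raise ValueError("G is constant; CIT undefined")
    if set(np.unique(T)) - {0.0, 1.0}:
        raise ValueError("T must be binary 0/1")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations; component-4 p is coarse")
    rng = np.random.default_rng(seed)
    n = len(L)
    one = np.ones(n)

    # (1) T ~ L
    p1 = logit(np.column_stack([one, L]), T, check_rank=False).pvalues[-1]
    # (2) L ~ G | T
    p2 = ols(np.column_stack([one, T, G]), L, check_rank=False).pvalues[-1]
    # (3) T ~ G | L
    p3 = logit(np.column_stack([one, L, G]), T, check_rank=False).pvalues[-1]

    # (4) equivalence test of L independent of T given G
    f_obs = _wald_chi2_last(np.column_stack([one, G, L]), T)
    gl_fit = ols(np.column_stack([one, L]), G, check_rank=False)
    fitted = gl_fit.params[0] + gl_fit.params[1] * L
    resid = G - fitted
    at_or_below = 0
    for _ in range(n_permutations):
        g_star = fitted + rng.permutation(resid)
        f_star = _wald_chi2_last(np.column_stack([one, g_star, L]), T)
        if f_star <= f_obs:
            at_or_below += 1
    p4 = (1 + at_or_below) / (n_permutations + 1)

    return CITResult(
        p_assoc_LT=float(p1),
        p_assoc_LG_given_T=float(p2),
        p_assoc_GT_given_L=float(p3),
        p_indep_LT_given_G=float(p4),
        n_permutations=n_permutations,
        seed=seed,
    )


def select_risk_haplotype(haplotype_counts) -> dict:
    """Pick the haplotype most associated with case status.

    ``haplotype_counts``: mapping or DataFrame of haplotype id ->
    (case_count, control_count). Each haplotype is tested in a 2x2
    chi-square of (this haplotype vs all others) x (case vs control);
    the haplotype minimizing p is returned. When any expected cell count
    is below 5 the Yates continuity correction is applied and flagged.
    Exact ties are broken lexicographically by haplotype id and flagged.
    """
    import pandas as pd

    if isinstance(haplotype_counts, pd.DataFrame):
        table = haplotype_counts[["case", "control"]]
    else:
        table = pd.DataFrame(haplotype_counts, index=["case", "control"]).T
        table.columns = ["case", "control"]
    if len(table) < 2:
        raise ValueError("need at least 2 haplotypes")
    tot_case, tot_ctrl = table["case"].sum(), table["control"].sum()
    if tot_case <= 0 or tot_ctrl <= 0:
        raise ValueError("both groups need positive totals")
    rows = []
    for hap in table.index:
        a, b = table.loc[hap, "case"], table.loc[hap, "control"]
        tab = np.array([[a, b], [tot_case - a, tot_ctrl - b]], dtype=float)
        if tab.sum() == 0:
            continue
        exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        corrected = bool((exp < 5).any())
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=corrected)
        rows.append({"haplotype": str(hap), "chi_square": float(chi2),
                     "p": float(p), "continuity_corrected": corrected})
    res = pd.DataFrame(rows).sort_values(["p", "haplotype"]).reset_index(drop=True)
    best = res.iloc[0]
    tie = bool(len(res) > 1 and np.isclose(res.iloc[1]["p"], best["p"]))
    return {
        "haplotype": best["haplotype"],
        "chi_square": best["chi_square"],
        "p": best["p"],
        "continuity_corrected": bool(best["continuity_corrected"]),
        "tie": tie,
        "all": res,
    }
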