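"""Cis-window methQTL testing and SNP association.

Each CpG's beta value is tested for genotype-group differences over all
SNPs within +/-18 kb (closed bounds, 1-based coordinates) via one-way
ANOVA across the AA/AB/BB dosage groups. A differentially methylated
position counts as "modulated by genotype" when at least one tested SNP
passes the alpha policy (Bonferroni within its cis window by default).
A 2x2 Fisher exact test on allele counts gives per-SNP case/control
association statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import BetaMatrix, GenotypeTable, ProbeAnnotation

__all__ = [
    "MetQTLResult", "cis_window", "metqtl_anova", "scan_methqtl",
    "proportion_modulated", "snp_association", "CIS_HALF_WIDTH",
]

CIS_HALF_WIDTH = 18_000  # +/-18 kb (36 kb window)


@dataclass
class MetQTLResult:
    cpg_id: str
    snp_id: str
    distance: int
    F: float
    p: float
    significant: bool = False
    flagged: str = ""


def cis_window(
    cpg: pd.Series,
    snps: GenotypeTable,
    half_width: int = CIS_HALF_WIDTH,
) -> np.ndarray:
    """Boolean mask of SNPs within the closed +/-half_width window of a CpG.

    ``cpg`` is one probe-annotation row (needs ``chromosome`` and
    ``position``). An empty result is allowed.
    """
    same = snps.chromosome == cpg["chromosome"]
    dist = np.abs(snps.position - int(cpg["position"]))
    return same & (dist <= half_width)


def metqtl_anova(beta_i: np.ndarray, dosage: np.ndarray,
                 cpg_id: str = "cpg", snp_id: str = "snp",
                 distance: int = 0) -> MetQTLResult:
    """One-way ANOVA of beta across genotype groups (AA/AB/BB).

    Missing dosages are excluded pairwise. Requires >= 2 groups with >= 2
    samples each. Zero within-group variance with unequal means gives the
    smallest representable p, flagged.
    """
    beta_i = np.asarray(beta_i, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    ok = np.isfinite(dosage) & np.isfinite(beta_i)
    groups = [beta_i[ok & (dosage == g)] for g in (0, 1, 2)]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need at least 2 genotype groups with >= 2 samples each")
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = np.array([g.mean() for g in groups])
    if within == 0:
        if np.allclose(means, means[0]):
            return MetQTLResult(cpg_id, snp_id, distance, 0.0, 1.0)
        return MetQTLResult(cpg_id, snp_id, distance, np.inf,
                            float(np.nextafter(0, 1)), flagged="zero within-group variance")
    F, p = stats.f_oneway(*groups)
    return MetQTLResult(cpg_id, snp_id, distance, float(F), float(p))


def scan_methqtl(
    beta: BetaMatrix,
    genotypes: GenotypeTable,
    annotation: ProbeAnnotation,
    cpg_ids: list | None = None,
    half_width: int = CIS_HALF_WIDTH,
    alpha: float = 0.05,
    alpha_policy: str = "bonferroni",
) -> pd.DataFrame:
    """Test every (CpG, cis SNP) pair for the chosen CpGs.

    ``alpha_policy``: "bonferroni" corrects alpha within each CpG's cis
    window (alpha / m tested SNPs); "nominal" uses alpha directly.
    """
    if alpha_policy not in ("bonferroni", "nominal"):
        raise ValueError(f"unknown alpha policy {alpha_policy!r}")
    cpg_ids = list(cpg_ids) if cpg_ids is not None else list(beta.cpg_ids)
    ann = annotation.table.set_index("cpg_id")
    beta_idx = pd.Index(beta.cpg_ids)
    rows = []
    for cid in cpg_ids:
        entry = ann.loc[cid]
        mask = cis_window(entry, genotypes, half_width)
        snp_rows = np.flatnonzero(mask)
        m = len(snp_rows)
        cut = alpha / m if (alpha_policy == "bonferroni" and m) else alpha
        b = beta.values[beta_idx.get_loc(cid)]
        for r in snp_rows:
            dist = int(abs(genotypes.position[r] - int(entry["position"])))
            try:
                res = metqtl_anova(b, genotypes.dosages[r], cid,
                                   genotypes.snp_ids[r], dist)
            except ValueError:
                continue  # degenerate grouping: untestable pair
            res.significant = bool(res.p < cut)
            rows.append(res)
    cols = ["cpg_id", "snp_id", "distance", "F", "p", "significant", "flagged"]
    return pd.DataFrame([r.__dict__ for r in rows], columns=cols)


def proportion_modulated(dmp_ids: list, metqtl_results: pd.DataFrame) -> dict:
    """Fraction of DMPs with at least one significant (meth)QTL SNP."""
    dmp_ids = list(dmp_ids)
    sig = set(metqtl_results.loc[metqtl_results["significant"], "cpg_id"])
    modulated = sum(1 for c in dmp_ids if c in sig)
    total = len(dmp_ids)
    return {
        "modulated": modulated,
        "total": total,
        "fraction": modulated / total if total else 0.0,
    }


def snp_association(table: np.ndarray) -> dict:
    """Two-sided Fisher exact test on a 2x2 allele-count table.

    ``table`` rows are case/control, columns risk/other allele counts.
    The odds ratio uses the Haldane-Anscombe 0.5 correction when any cell
    is zero.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a non-negative 2x2 count table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero margin; association undefined")
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    if (tab == 0).any():
        t = tab + 0.5
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        corrected = True
    else:
        odds = (tab[0, 0] * tab[1, 1]) / (tab[0, 1] * tab[1, 0])
        corrected = False
    return {"odds_ratio": float(odds), "p": float(p), "haldane": corrected}
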