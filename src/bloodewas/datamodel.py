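"""Core containers and quality-control operations.

The central measurement object is a CpG-by-sample matrix of beta values
(methylated fraction, in [0, 1]). Linear modelling is done on the logit2
("M value") scale; conversions between the two live here, together with
probe/sample/genotype filters and the case-control effect size
(delta-beta). Missing measurements are represented as NaN; the logit
transform refuses them so that downstream models never see silent holes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BetaMatrix",
    "MValueMatrix",
    "ProbeAnnotation",
    "SampleMeta",
    "GenotypeTable",
    "FilterReport",
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "filter_samples",
    "genotype_qc",
    "delta_beta",
    "hwe_chi_square",
]

DEFAULT_M_EPSILON = 1e-3  # clip bound for the logit transform; keeps |M| <= ~10


def _check_unique(ids: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if len(set(arr)) != len(arr):
        dupes = pd.Index(arr)[pd.Index(arr).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return arr


@dataclass
class _IdMatrix:
    """Shared shape/id validation for CpG-by-sample matrices."""

    values: np.ndarray
    cpg_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (CpG x sample) matrix")
        self.cpg_ids = _check_unique(self.cpg_ids, "CpG ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame):
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(), df.columns.to_numpy())


@dataclass
class BetaMatrix(_IdMatrix):
    """Methylation fractions in [0, 1]; NaN marks a missing measurement."""

    def __post_init__(self):
        super().__post_init__()
        vals = self.values
        finite = vals[np.isfinite(vals)]
        if np.isinf(vals).any():
            raise ValueError("beta matrix contains infinite values")
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere((vals < 0) | (vals > 1))
            i, j = bad[0]
            raise ValueError(
                f"beta value out of [0,1] at CpG {self.cpg_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {vals[i, j]}"
            )


@dataclass
class MValueMatrix(_IdMatrix):
    """Logit2-scale methylation; always finite."""

    def __post_init__(self):
        super().__post_init__()
        if not np.isfinite(self.values).all():
            raise ValueError("M-value matrix must be finite")


@dataclass
class ProbeAnnotation:
    """Per-CpG genomic annotation (1-based positions, closed intervals)."""

    table: pd.DataFrame  # columns: cpg_id, chromosome, position, gene

    def __post_init__(self):
        required = {"cpg_id", "chromosome", "position"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if "gene" not in self.table.columns:
            self.table = self.table.assign(gene="")
        _check_unique(self.table["cpg_id"].to_numpy(), "annotation CpG ids")
        pos = self.table["position"].to_numpy()
        if not np.issubdtype(np.asarray(pos).dtype, np.number) or (pos <= 0).any():
            raise ValueError("positions must be positive integers (1-based)")
        self.table = self.table.reset_index(drop=True)

    def lookup(self, cpg_ids: Iterable[str]) -> pd.DataFrame:
        sub = self.table.set_index("cpg_id").loc[list(cpg_ids)]
        return sub.reset_index()


@dataclass
class SampleMeta:
    """Sample covariates: phenotype (0=control, 1=case), age, sex, region, batch."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"sample_id", "phenotype", "age", "sex", "region"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        _check_unique(self.table["sample_id"].to_numpy(), "sample ids")
        ph = self.table["phenotype"]
        if ph.isna().any():
            raise ValueError("phenotype may not be missing")
        if not set(np.unique(ph)) <= {0, 1}:
            raise ValueError("phenotype must be binary 0/1")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy()

    @property
    def phenotype(self) -> np.ndarray:
        return self.table["phenotype"].to_numpy(dtype=int)

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleMeta":
        sub = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleMeta(sub)


@dataclass
class GenotypeTable:
    """SNP-by-sample risk-allele dosages in {0,1,2}; NaN marks a missing call."""

    dosages: np.ndarray  # (n_snps, n_samples)
    snp_ids: np.ndarray
    sample_ids: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray  # 1-based

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = _check_unique(self.snp_ids, "SNP ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        if self.dosages.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("dosage shape inconsistent with ids")
        if len(self.chromosome) != len(self.snp_ids) or len(self.position) != len(self.snp_ids):
            raise ValueError("chromosome/position must align to SNP ids")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be in {0,1,2} or missing (NaN)")
        if (self.position <= 0).any():
            raise ValueError("positions must be positive (1-based)")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def dosage_of(self, snp_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in table")
        return self.dosages[idx[0]]

    def subset_snps(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            self.dosages[mask], self.snp_ids[mask], self.sample_ids,
            self.chromosome[mask], self.position[mask],
        )


@dataclass
class FilterReport:
    """What a filter removed and why."""

    removed: list = field(default_factory=list)  # (id, reason) pairs
    flagged: list = field(default_factory=list)

    @property
    def removed_ids(self) -> list:
        return [i for i, _ in self.removed]


# ---------------------------------------------------------------------------
# beta <-> M


def beta_to_m(beta: BetaMatrix, epsilon: float = DEFAULT_M_EPSILON) -> MValueMatrix:
    """M = log2(beta / (1 - beta)) after clipping beta into [eps, 1-eps]."""
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    vals = beta.values
    if not np.isfinite(vals).all():
        i, j = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite beta at CpG {beta.cpg_ids[i]!r}, sample "
            f"{beta.sample_ids[j]!r}; filter or impute before transforming"
        )
    clipped = np.clip(vals, epsilon, 1.0 - epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    return MValueMatrix(m, beta.cpg_ids.copy(), beta.sample_ids.copy())


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse logit2: beta = 2^M / (1 + 2^M)."""
    vals = m.values
    if not np.isfinite(vals).all():
        raise ValueError("M-value matrix must be finite")
    # expit(M * ln 2), numerically stable at both tails
    beta = stats.logistic.cdf(vals * np.log(2.0))
    return BetaMatrix(beta, m.cpg_ids.copy(), m.sample_ids.copy())


# ---------------------------------------------------------------------------
# probe / sample filters


def filter_probes(
    beta: BetaMatrix,
    detection_p: np.ndarray | None = None,
    p_cut: float = 0.01,
    max_fail_fraction: float = 0.05,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove probes failing detection in too many samples.

    A probe fails in a sample when its detection p-value exceeds ``p_cut``
    or its beta is missing; the probe is removed when the failing fraction
    of samples exceeds ``max_fail_fraction``. Without detection p-values
    only missingness counts.
    """
    report = FilterReport()
    fails = ~np.isfinite(beta.values)
    if detection_p is not None:
        detection_p = np.asarray(detection_p, dtype=float)
        if detection_p.shape != beta.values.shape:
            raise ValueError("detection_p must align with the beta matrix")
        fails = fails | (detection_p > p_cut)
    fail_frac = fails.mean(axis=1)
    keep = fail_frac <= max_fail_fraction
    for i in np.flatnonzero(~keep):
        report.removed.append(
            (beta.cpg_ids[i], f"detection failure in {fail_frac[i]:.1%} of samples")
        )
    if not keep.any():
        raise ValueError("probe filter removed every probe; check thresholds")
    out = BetaMatrix(beta.values[keep], beta.cpg_ids[keep], beta.sample_ids.copy())
    return out, report


def filter_samples(
    beta: BetaMatrix, max_fail_fraction: float = 0.1
) -> tuple[BetaMatrix, FilterReport]:
    """Remove samples with too high a fraction of missing probe values."""
    report = FilterReport()
    fail_frac = (~np.isfinite(beta.values)).mean(axis=0)
    keep = fail_frac <= max_fail_fraction
    for j in np.flatnonzero(~keep):
        report.removed.append(
            (beta.sample_ids[j], f"missing in {fail_frac[j]:.1%} of probes")
        )
    if not keep.any():
        raise ValueError("sample filter removed every sample; check thresholds")
    out = BetaMatrix(beta.values[:, keep], beta.cpg_ids.copy(), beta.sample_ids[keep])
    return out, report


# ---------------------------------------------------------------------------
# genotype QC


def hwe_chi_square(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Returns (chi_square, p). Raises on a monomorphic SNP (expected
    heterozygote count zero), which callers should skip rather than test.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotype calls")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        raise ValueError("monomorphic SNP: HWE test undefined")
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def genotype_qc(
    g: GenotypeTable,
    min_snp_call: float = 0.98,
    min_sample_call: float = 0.95,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeTable, FilterReport]:
    """SNP call-rate, then sample call-rate, then HWE filtering (fixed order).

    Monomorphic SNPs cannot be HWE-tested; they are retained and flagged.
    """
    report = FilterReport()
    called = np.isfinite(g.dosages)

    snp_call = called.mean(axis=1)
    keep_snp = snp_call >= min_snp_call
    for i in np.flatnonzero(~keep_snp):
        report.removed.append((g.snp_ids[i], f"SNP call rate {snp_call[i]:.3f} < {min_snp_call}"))
    g = g.subset_snps(keep_snp)

    called = np.isfinite(g.dosages)
    sample_call = called.mean(axis=0) if g.n_snps else np.ones(len(g.sample_ids))
    keep_sample = sample_call >= min_sample_call
    for j in np.flatnonzero(~keep_sample):
        report.removed.append(
            (g.sample_ids[j], f"sample call rate {sample_call[j]:.3f} < {min_sample_call}")
        )
    g = GenotypeTable(
        g.dosages[:, keep_sample], g.snp_ids, g.sample_ids[keep_sample],
        g.chromosome, g.position,
    )

    keep_hwe = np.ones(g.n_snps, dtype=bool)
    for i in range(g.n_snps):
        d = g.dosages[i]
        d = d[np.isfinite(d)]
        counts = [(d == k).sum() for k in (0, 1, 2)]
        try:
            chi2, p = hwe_chi_square(*counts)
        except ValueError:
            report.flagged.append((g.snp_ids[i], "monomorphic; HWE test skipped"))
            continue
        if p < hwe_alpha:
            keep_hwe[i] = False
            report.removed.append((g.snp_ids[i], f"HWE p={p:.3g} < {hwe_alpha}"))
    return g.subset_snps(keep_hwe), report


# ---------------------------------------------------------------------------
# effect size


def delta_beta(beta: BetaMatrix, phenotype: np.ndarray) -> pd.Series:
    """Per-CpG mean(case beta) - mean(control beta).

    Positive values mean hypermethylation in cases. NaN betas are excluded
    pairwise.
    """
    phenotype = np.asarray(phenotype)
    if phenotype.shape != (beta.n_samples,):
        raise ValueError("phenotype must align with the samples")
    case = phenotype == 1
    ctrl = phenotype == 0
    if not case.any() or not ctrl.any():
        raise ValueError("both case and control groups must be non-empty")
    with np.errstate(invalid="ignore"):
        d = np.nanmean(beta.values[:, case], axis=1) - np.nanmean(
            beta.values[:, ctrl], axis=1
        )
    return pd.Series(d, index=beta.cpg_ids, name="delta_beta")
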