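"""TSV and VCF readers/writers for the package's data containers.

All tabular formats are plain TSV (gzip-transparent through pandas):

* beta matrix — first column ``cpg_id``, remaining columns one per sample;
* probe annotation — ``cpg_id  chromosome  position  gene``;
* sample metadata — ``sample_id  phenotype  age  sex  region  [batch]``;
* genotype dosages — ``snp_id  chromosome  position`` then one column per
  sample holding the count of the effect allele (0/1/2, blank = missing).

Genotypes can also come from a VCF: the GT field is converted to the
dosage of the ALT allele (the stated effect allele).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, GenotypeTable, ProbeAnnotation, SampleMeta

__all__ = [
    "read_beta_tsv", "write_beta_tsv",
    "read_annotation_tsv", "write_annotation_tsv",
    "read_meta_tsv", "write_meta_tsv",
    "read_genotypes_tsv", "write_genotypes_tsv",
    "read_genotypes_vcf",
]

_GENO_META_COLS = ["snp_id", "chromosome", "position"]


def read_beta_tsv(path) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BetaMatrix.from_frame(df)


def write_beta_tsv(beta: BetaMatrix, path, float_format: str = "%.6g") -> None:
    beta.to_frame().rename_axis("cpg_id").to_csv(
        path, sep="\t", float_format=float_format
    )


def read_annotation_tsv(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if "gene" in df.columns:
        df["gene"] = df["gene"].fillna("")
    return ProbeAnnotation(df)


def write_annotation_tsv(ann: ProbeAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_meta_tsv(path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str, "region": str})
    return SampleMeta(df)


def write_meta_tsv(meta: SampleMeta, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chromosome": str})
    missing = [c for c in _GENO_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in _GENO_META_COLS]
    dosages = df[sample_cols].to_numpy(dtype=float)
    return GenotypeTable(
        dosages,
        df["snp_id"].to_numpy(),
        np.asarray(sample_cols, dtype=object),
        df["chromosome"].to_numpy(),
        df["position"].to_numpy(),
    )


def write_genotypes_tsv(g: GenotypeTable, path) -> None:
    df = pd.DataFrame(g.dosages, columns=g.sample_ids)
    df.insert(0, "snp_id", g.snp_ids)
    df.insert(1, "chromosome", g.chromosome)
    df.insert(2, "position", g.position)
    df.to_csv(path, sep="\t", index=False, float_format="%.0f")


def read_genotypes_vcf(path) -> GenotypeTable:
    """Read GT genotypes from a VCF into ALT-allele dosages.

    Multi-allelic records are rejected; missing GT becomes NaN.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading VCF requires the optional cyvcf2 dependency "
            "(pip install bloodewas[vcf])"
        ) from exc
    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    snp_ids, chroms, positions, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic VCF record at {var.CHROM}:{var.POS}")
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        gts = var.genotype.array()[:, :2].astype(float)
        gts[gts < 0] = np.nan
        rows.append(np.where(np.isnan(gts).any(axis=1), np.nan, (gts > 0).sum(axis=1)))
    return GenotypeTable(
        np.asarray(rows, dtype=float).reshape(len(snp_ids), len(samples)),
        np.asarray(snp_ids, dtype=object),
        samples,
        np.asarray(chroms, dtype=object),
        np.asarray(positions, dtype=np.int64),
    )
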