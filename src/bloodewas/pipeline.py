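"""End-to-end orchestration: simulate/load -> QC -> deconvolve -> EWAS ->
genotype-risk-corrected EWAS -> scores/ROC -> cell-specific DMPs -> CIT
mediation -> cis-methQTL -> report.

Every stochastic stage draws from a seed derived deterministically from
the run seed, so identical config + seed gives byte-identical outputs.
Outputs are TSV/JSON files plus a manifest with SHA-256 hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .cellspecific import run_csdmp_scan, summarize_csdmp
from .datamodel import BetaMatrix, beta_to_m, delta_beta, filter_probes, filter_samples, genotype_qc
from .deconvolution import compare_fractions, estimate_fractions, CellFractions
from .ewas import combine_dmr, dmr_to_bed, run_ewas, run_grc_ewas
from .mediation import cit_test
from .metqtl import proportion_modulated, scan_methqtl
from .riskscores import combine_scores, grc_meth_score, hla_score, prs_score, roc_auc
from .simulate import HLA_TAG_SNP, SimCohort, SimConfig, generate_cohort

log = logging.getLogger("bloodewas")

__all__ = ["RunConfig", "run_all", "make_report", "load_config"]

STAGES = ["simulate", "qc", "deconvolve", "ewas", "grc_ewas", "scores",
          "csdmp", "cit", "metqtl", "report"]


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    p_threshold: float = 9.8e-8
    delta_beta_cut: float = 0.02
    estimate_cut: float = 2.0
    cis_half_width: int = 18_000
    methqtl_alpha: float = 0.05
    methqtl_alpha_policy: str = "bonferroni"
    dmr_max_gap: int = 1000
    dmr_min_cpgs: int = 3
    test_fraction: float = 0.5
    cit_permutations: int = 200
    seed: int = 0
    outdir: str = "bloodewas_run"
    write_inputs: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim_d = d.pop("sim", {}) or {}
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim_d) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
        if "cell_types" in sim_d:
            sim_d["cell_types"] = tuple(sim_d["cell_types"])
        cfg = cls(sim=SimConfig(**sim_d), **d)
        # the run seed drives the simulation unless one was given explicitly
        if "seed" not in sim_d:
            cfg = dataclasses.replace(cfg, sim=cfg.sim.replace(seed=cfg.seed))
        return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _seed(base: int, offset: int) -> int:
    return int((base * 1000 + offset) % (2**31 - 1))


def _write_tsv(df: pd.DataFrame, path: Path, index=False):
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")
    return path


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Run the whole chain; returns the in-memory outputs and writes files.

    Any stage failure aborts with the stage name and the offending record.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    written: list[Path] = []
    t0 = time.time()

    def stage(name):
        log.info("stage %-10s start (t=%.1fs)", name, time.time() - t0)

    try:
        stage("simulate")
        cohort = generate_cohort(config.sim)
        results["cohort"] = cohort
        if config.write_inputs:
            bio.write_beta_tsv(cohort.beta, out / "beta.tsv")
            bio.write_meta_tsv(cohort.meta, out / "meta.tsv")
            bio.write_genotypes_tsv(cohort.genotypes, out / "genotypes.tsv")
            bio.write_annotation_tsv(cohort.annotation, out / "annotation.tsv")
            written += [out / f for f in
                        ("beta.tsv", "meta.tsv", "genotypes.tsv", "annotation.tsv")]
    except Exception as e:
        raise PipelineError("simulate", e) from e

    try:
        stage("qc")
        beta, probe_rep = filter_probes(cohort.beta)
        beta, sample_rep = filter_samples(beta)
        geno, geno_rep = genotype_qc(cohort.genotypes)
        meta = cohort.meta.aligned_to(beta.sample_ids)
        qc = pd.DataFrame(
            probe_rep.removed + sample_rep.removed + geno_rep.removed,
            columns=["id", "reason"])
        results.update(beta=beta, genotypes=geno, meta=meta, qc=qc)
        written.append(_write_tsv(qc, out / "qc_removed.tsv"))
    except Exception as e:
        raise PipelineError("qc", e) from e

    try:
        stage("deconvolve")
        sig_mask = np.isin(cohort.reference.cpg_ids, cohort.signature_cpgs)
        reference = BetaMatrix(cohort.reference.values[sig_mask],
                               cohort.reference.cpg_ids[sig_mask],
                               cohort.reference.sample_ids.copy())
        fractions = estimate_fractions(beta, reference)
        frac_cmp = compare_fractions(fractions, meta.phenotype)
        results.update(fractions=fractions, fraction_comparison=frac_cmp)
        written.append(_write_tsv(
            fractions.table.rename_axis("sample_id"), out / "fractions.tsv", index=True))
        written.append(_write_tsv(frac_cmp, out / "fraction_comparison.tsv"))
    except Exception as e:
        raise PipelineError("deconvolve", e) from e

    try:
        stage("ewas")
        dmps = run_ewas(beta, meta, fractions,
                        p_threshold=config.p_threshold,
                        delta_beta_cut=config.delta_beta_cut)
        dmrs = combine_dmr(dmps, cohort.annotation,
                           max_gap=config.dmr_max_gap, min_cpgs=config.dmr_min_cpgs)
        results.update(dmps=dmps, dmrs=dmrs)
        written.append(_write_tsv(dmps, out / "ewas_dmps.tsv"))
        dmr_df = pd.DataFrame([{
            "chromosome": d.chromosome, "start": d.start, "end": d.end,
            "n_cpgs": len(d.cpg_ids), "fisher_p": d.fisher_p,
            "stouffer_p": d.stouffer_p, "harmonic_mean_fdr": d.harmonic_mean_fdr,
            "significant": d.significant} for d in dmrs])
        written.append(_write_tsv(dmr_df, out / "dmrs.tsv"))
        written.append(_write_tsv(dmr_to_bed(dmrs), out / "dmrs.bed"))
    except Exception as e:
        raise PipelineError("ewas", e) from e

    try:
        stage("grc_ewas")
        hla = hla_score(geno, HLA_TAG_SNP).loc[list(meta.sample_ids)].to_numpy()
        prs = prs_score(geno, cohort.truth.prs_weights).loc[list(meta.sample_ids)].to_numpy()
        grc = run_grc_ewas(beta, meta, fractions, hla, prs,
                           p_threshold=config.p_threshold,
                           delta_beta_cut=config.delta_beta_cut)
        results.update(grc_dmps=grc, hla=hla, prs=prs)
        written.append(_write_tsv(grc, out / "grc_dmps.tsv"))
    except Exception as e:
        raise PipelineError("grc_ewas", e) from e

    try:
        stage("scores")
        scores = _score_stage(config, beta, meta, fractions, hla, prs)
        results["scores"] = scores
        written.append(_write_tsv(scores["table"], out / "scores.tsv", index=True))
        written.append(_write_tsv(scores["auc_table"], out / "roc_auc.tsv"))
    except Exception as e:
        raise PipelineError("scores", e) from e

    try:
        stage("csdmp")
        m = beta_to_m(beta)
        cs = run_csdmp_scan(m, fractions, meta,
                            estimate_cut=config.estimate_cut,
                            p_cut=config.p_threshold)
        cs_summary = summarize_csdmp(cs)
        results.update(csdmp=cs, csdmp_summary=cs_summary)
        written.append(_write_tsv(cs, out / "csdmp.tsv"))
        (out / "csdmp_summary.json").write_text(json.dumps(cs_summary, indent=2))
        written.append(out / "csdmp_summary.json")
    except Exception as e:
        raise PipelineError("csdmp", e) from e

    try:
        stage("cit")
        cit_rows = []
        sig_dmrs = [d for d in results["dmrs"] if d.significant]
        pmap = results["dmps"].set_index("cpg_id")["p"]
        for k, d in enumerate(sig_dmrs):
            index_cpg = min(d.cpg_ids, key=lambda c: (pmap.get(c, 1.0), c))
            g = beta.values[pd.Index(beta.cpg_ids).get_loc(index_cpg)]
            res = cit_test(hla, g, meta.phenotype,
                           n_permutations=config.cit_permutations,
                           seed=_seed(config.seed, 100 + k))
            cit_rows.append({
                "dmr": f"{d.chromosome}:{d.start}-{d.end}", "index_cpg": index_cpg,
                "p_assoc_LT": res.p_assoc_LT,
                "p_assoc_LG_given_T": res.p_assoc_LG_given_T,
                "p_assoc_GT_given_L": res.p_assoc_GT_given_L,
                "p_indep_LT_given_G": res.p_indep_LT_given_G,
                "omnibus_p": res.omnibus_p,
            })
        cit_df = pd.DataFrame(cit_rows, columns=[
            "dmr", "index_cpg", "p_assoc_LT", "p_assoc_LG_given_T",
            "p_assoc_GT_given_L", "p_indep_LT_given_G", "omnibus_p"])
        results["cit"] = cit_df
        written.append(_write_tsv(cit_df, out / "cit.tsv"))
    except Exception as e:
        raise PipelineError("cit", e) from e

    try:
        stage("metqtl")
        sig_cpgs = results["grc_dmps"].loc[results["grc_dmps"]["significant"], "cpg_id"]
        qtl = scan_methqtl(beta, geno, cohort.annotation, list(sig_cpgs),
                           half_width=config.cis_half_width,
                           alpha=config.methqtl_alpha,
                           alpha_policy=config.methqtl_alpha_policy)
        modulation = proportion_modulated(list(sig_cpgs), qtl)
        results.update(metqtl=qtl, modulation=modulation)
        written.append(_write_tsv(qtl, out / "metqtl.tsv"))
        (out / "modulation.json").write_text(json.dumps(modulation, indent=2))
        written.append(out / "modulation.json")
    except Exception as e:
        raise PipelineError("metqtl", e) from e

    try:
        stage("report")
        report = make_report(results)
        (out / "report.md").write_text(report)
        written.append(out / "report.md")
        manifest = {
            "seed": config.seed,
            "version": _pkg_version(),
            "outputs": {p.name: _sha256(p) for p in sorted(written)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest"] = manifest
        results["report"] = report
    except Exception as e:
        raise PipelineError("report", e) from e
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return results


def _score_stage(config, beta, meta, fractions, hla, prs):
    """Train/test split scoring: weights and model fits on the training
    half, AUCs reported both held-out and in-sample (labeled)."""
    rng = np.random.default_rng(_seed(config.seed, 7))
    pheno = meta.phenotype
    n = len(pheno)
    test_mask = np.zeros(n, dtype=bool)
    for g in (0, 1):  # stratified split
        idx = np.flatnonzero(pheno == g)
        k = int(round(config.test_fraction * len(idx)))
        test_mask[rng.choice(idx, size=k, replace=False)] = True
    train, test = ~test_mask, test_mask

    def subset(mask):
        ids = beta.sample_ids[mask]
        return (BetaMatrix(beta.values[:, mask], beta.cpg_ids.copy(), ids),
                meta.aligned_to(ids))

    beta_tr, meta_tr = subset(train)
    beta_te, meta_te = subset(test)
    frac_tr = CellFractions(fractions.table.loc[list(beta_tr.sample_ids)])
    grc_tr = run_grc_ewas(beta_tr, meta_tr, frac_tr, hla[train], prs[train],
                          p_threshold=config.p_threshold,
                          delta_beta_cut=config.delta_beta_cut)
    sel = grc_tr[grc_tr["significant"]]
    selection = "genome-wide significant"
    if len(sel) == 0:
        # small-cohort fallback: no CpG reaches genome-wide significance,
        # so take the strongest associations instead (recorded as such)
        est = grc_tr.dropna(subset=["p"]).sort_values(["p", "cpg_id"])
        sel = est.head(10)
        selection = "top 10 by p (none genome-wide significant)"
    if len(sel) == 0:
        raise ValueError("no estimable CpGs; cannot build a methylation score")
    weights = pd.Series(sel["delta_beta"].to_numpy(), index=sel["cpg_id"].to_numpy())
    meth = grc_meth_score(beta, weights)

    table = pd.DataFrame({
        "grc_meth_score": meth.to_numpy(), "hla": hla, "prs": prs,
        "phenotype": pheno, "split": np.where(test_mask, "test", "train"),
    }, index=beta.sample_ids).rename_axis("sample_id")

    genetic_fit = combine_scores(table.loc[train, ["hla", "prs"]], pheno[train])
    co = genetic_fit["coefficients"]
    genetic_all = co.get("intercept", 0.0) + table["hla"] * co.get("hla", 0.0) \
        + table["prs"] * co.get("prs", 0.0)
    table["genetic_score"] = genetic_all

    rows = []
    for name, col in (("grc_meth_score", "grc_meth_score"),
                      ("genetic_score", "genetic_score")):
        for split, mask in (("held_out", test), ("in_sample", train)):
            r = roc_auc(table[col].to_numpy()[mask], pheno[mask])
            rows.append({"score": name, "split": split, "auc": r.auc,
                         "ci_low": r.ci_low, "ci_high": r.ci_high})
    combined_fit = combine_scores(
        table.loc[train, ["grc_meth_score", "hla", "prs"]], pheno[train])
    cc = combined_fit["coefficients"]
    combined = (cc.get("intercept", 0.0)
                + table["grc_meth_score"] * cc.get("grc_meth_score", 0.0)
                + table["hla"] * cc.get("hla", 0.0)
                + table["prs"] * cc.get("prs", 0.0))
    table["combined_score"] = combined
    for split, mask in (("held_out", test), ("in_sample", train)):
        r = roc_auc(combined.to_numpy()[mask], pheno[mask])
        rows.append({"score": "combined", "split": split, "auc": r.auc,
                     "ci_low": r.ci_low, "ci_high": r.ci_high})
    auc_table = pd.DataFrame(rows)
    return {"table": table, "auc_table": auc_table, "weights": weights,
            "n_score_cpgs": len(weights), "selection": selection,
            "test_mask": test_mask}


def make_report(results: dict) -> str:
    """Deterministic markdown summary of a run; absent stages are marked."""
    lines = ["# bloodewas run report", ""]

    def section(title):
        lines.extend([f"## {title}", ""])

    section("Cell fractions")
    if "fraction_comparison" in results:
        lines.append(results["fraction_comparison"].to_string(index=False))
    else:
        lines.append("(stage absent)")
    lines.append("")

    section("EWAS")
    if "dmps" in results:
        d = results["dmps"]
        lines.append(f"significant DMPs: {int(d['significant'].sum())} of {len(d)}")
        lines.append(
            "significant with large effect: "
            f"{int((d['significant'] & d['large_effect']).sum())}")
        n_sig_dmr = sum(x.significant for x in results.get("dmrs", []))
        lines.append(f"significant DMRs: {n_sig_dmr} of {len(results.get('dmrs', []))}")
    else:
        lines.append("(stage absent)")
    lines.append("")

    section("Genotype-risk-corrected EWAS")
    if "grc_dmps" in results:
        g = results["grc_dmps"]
        lines.append(f"significant DMPs after correction: {int(g['significant'].sum())}")
    else:
        lines.append("(stage absent)")
    lines.append("")

    section("Risk scores (AUC)")
    if "scores" in results:
        lines.append(results["scores"]["auc_table"].to_string(index=False))
        lines.append(f"score CpGs: {results['scores']['n_score_cpgs']} "
                     f"({results['scores']['selection']})")
    else:
        lines.append("(stage absent)")
    lines.append("")

    section("Cell-type-specific DMPs")
    if "csdmp_summary" in results:
        for ct, c in sorted(results["csdmp_summary"]["per_cell_type"].items()):
            lines.append(f"{ct}: {c['n_csdmp']} csDMPs "
                         f"({c['n_hyper']} hyper / {c['n_hypo']} hypo)")
    else:
        lines.append("(stage absent)")
    lines.append("")

    section("CIT mediation")
    if "cit" in results and len(results["cit"]):
        lines.append(results["cit"].to_string(index=False))
    elif "cit" in results:
        lines.append("no significant DMRs to test")
    else:
        lines.append("(stage absent)")
    lines.append("")

    section("methQTL modulation")
    if "modulation" in results:
        m = results["modulation"]
        lines.append(f"{m['modulated']} of {m['total']} DMPs modulated "
                     f"({100 * m['fraction']:.1f}%)")
    else:
        lines.append("(stage absent)")
    lines.append("")
    return "\n".join(lines)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pkg_version() -> str:
    from . import __version__
    return __version__
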