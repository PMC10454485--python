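"""EWAS models, DMR combination and correlation against closed forms."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from bloodewas.datamodel import ProbeAnnotation, SampleMeta
from bloodewas.ewas import (
    DELTA_BETA_CUT, GENOME_WIDE_P, combine_dmr, dmr_to_bed,
    expr_meth_correlation, fit_dmp, run_ewas, run_grc_ewas, sensitivity_scan,
)
from conftest import make_beta


def _plain_meta(pheno):
    """Metadata whose covariates are constant (reduce to intercept-only)."""
    n = len(pheno)
    return SampleMeta(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)], "phenotype": pheno,
        "age": [40.0] * n, "sex": ["F"] * n, "region": ["r"] * n,
    }))


class TestFitDmp:
    def test_saturated_binary_log_odds_ratio(self):
        # x=1: 8 cases / 2 controls; x=0: 2 cases / 8 controls -> ln 16
        x = np.array([1.0] * 10 + [0.0] * 10)
        ph = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        with pytest.warns(UserWarning, match="collinear"):
            res = fit_dmp(x, _plain_meta(ph))
        assert res.coefficient == pytest.approx(np.log(16.0), abs=1e-5)

    def test_constant_beta_non_estimable(self):
        ph = np.array([1] * 5 + [0] * 5)
        with pytest.warns(UserWarning):
            res = fit_dmp(np.full(10, 0.4), _plain_meta(ph))
        assert not res.estimable and np.isnan(res.p)

    def test_separation_flagged_not_tiny_p(self):
        x = np.array([1.0] * 5 + [0.0] * 5)
        ph = np.array([1] * 5 + [0] * 5)
        with pytest.warns(UserWarning):
            res = fit_dmp(x, _plain_meta(ph))
        assert not res.estimable and np.isnan(res.p)

    def test_matches_statsmodels_with_covariates(self, rng):
        n = 120
        meta = SampleMeta(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "phenotype": rng.integers(0, 2, n),
            "age": rng.uniform(20, 60, n),
            "sex": rng.choice(["F", "M"], n),
            "region": rng.choice(["a", "b", "c"], n),
        }))
        b = rng.uniform(0.2, 0.8, n)
        res = fit_dmp(b, meta)
        t = meta.table
        X = pd.DataFrame({
            "const": 1.0, "age": t["age"],
            "sexM": (t["sex"] == "M").astype(float),
            "reg_b": (t["region"] == "b").astype(float),
            "reg_c": (t["region"] == "c").astype(float),
            "beta": b,
        })
        ref = sm.GLM(t["phenotype"], X, family=sm.families.Binomial()).fit()
        assert res.coefficient == pytest.approx(ref.params["beta"], abs=1e-6)
        assert res.p == pytest.approx(ref.pvalues["beta"], rel=1e-5)


class TestRunEwas:
    def test_null_p_values_roughly_uniform(self, rng):
        n, n_cpgs = 300, 300
        ph = np.array([1] * 100 + [0] * 200)
        meta = _plain_meta(ph)
        b = make_beta(np.clip(rng.normal(0.5, 0.05, size=(n_cpgs, n)), 0, 1))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_ewas(b, meta)
        frac = (res["p"] < 0.05).mean()
        assert 0.02 < frac < 0.09  # 3-sigma binomial band around 0.05
        assert res.attrs["n_significant"] == 0

    def test_label_swap_flips_delta_beta_keeps_p(self, rng):
        ph = np.array([1] * 30 + [0] * 30)
        b = make_beta(np.clip(rng.normal(0.5, 0.08, size=(20, 60)), 0, 1))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = run_ewas(b, _plain_meta(ph))
            r2 = run_ewas(b, _plain_meta(1 - ph))
        np.testing.assert_allclose(r1["delta_beta"], -r2["delta_beta"], atol=1e-12)
        np.testing.assert_allclose(r1["p"], r2["p"], rtol=1e-6)

    def test_default_thresholds_are_the_recorded_ones(self):
        assert GENOME_WIDE_P == 9.8e-8
        assert DELTA_BETA_CUT == 0.02

    def test_genotype_correction_removes_haplotype_driven_cpg(self, rng):
        """A CpG fully determined by a risk-haplotype dosage that drives the
        phenotype is significant in the plain EWAS but loses significance
        once the dosage is a covariate; a genotype-independent CpG stays."""
        n = 600
        dos = rng.binomial(2, 0.3, n).astype(float)
        cpg_geno = 0.2 + 0.2 * dos + rng.normal(0, 0.01, n)
        lp = np.log(3) * (dos - dos.mean())
        ph = (rng.random(n) < 1 / (1 + np.exp(-(lp - 0.5)))).astype(int)
        cpg_env = np.clip(0.5 + 0.04 * ph + rng.normal(0, 0.03, n), 0, 1)
        b = make_beta(np.vstack([np.clip(cpg_geno, 0, 1), cpg_env]))
        meta = _plain_meta(ph)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = run_ewas(b, meta)
            grc = run_grc_ewas(b, meta, None, dos, np.zeros(n))
        assert bool(plain.loc[0, "significant"])
        assert not bool(grc.loc[0, "significant"])
        assert bool(plain.loc[1, "significant"]) and bool(grc.loc[1, "significant"])


class TestSensitivity:
    def test_self_covariate_r2_one(self):
        b = make_beta([[0.1, 0.3, 0.5, 0.7]])
        res = sensitivity_scan(b, b.values[0])
        assert res.loc[0, "variance_explained"] == pytest.approx(1.0)

    def test_two_level_categorical_equals_t_test_squared(self, rng):
        vals = rng.uniform(0.2, 0.8, size=(5, 40))
        groups = np.array(["x"] * 20 + ["y"] * 20, dtype=object)
        res = sensitivity_scan(make_beta(vals), groups)
        for i in range(5):
            t, p = stats.ttest_ind(vals[i, :20], vals[i, 20:], equal_var=True)
            assert res.loc[i, "statistic"] == pytest.approx(t * t, rel=1e-10)
            assert res.loc[i, "p"] == pytest.approx(p, rel=1e-10)

    def test_independent_covariate_null_uniform(self, rng):
        vals = rng.uniform(0.2, 0.8, size=(400, 50))
        cov = rng.normal(size=50)
        res = sensitivity_scan(make_beta(vals), cov)
        assert 0.01 < (res["p"] < 0.05).mean() < 0.11

    def test_single_level_categorical_rejected(self):
        with pytest.raises(ValueError, match="two levels"):
            sensitivity_scan(make_beta([[0.1, 0.2]]), np.array(["a", "a"], dtype=object))


class TestCombineDmr:
    def _annotation(self, n, gap=500):
        return ProbeAnnotation(pd.DataFrame({
            "cpg_id": [f"cg{i}" for i in range(n)],
            "chromosome": "chr1",
            "position": 1000 + gap * np.arange(n),
        }))

    def _dmps(self, pvals):
        return pd.DataFrame({"cpg_id": [f"cg{i}" for i in range(len(pvals))],
                             "p": pvals})

    def test_all_member_p_one_not_significant(self):
        res = combine_dmr(self._dmps([1.0, 1.0, 1.0]), self._annotation(3))
        assert len(res) == 1
        d = res[0]
        assert d.fisher_p == pytest.approx(1.0)
        assert not d.significant

    def test_single_member_reduces_to_own_p(self):
        res = combine_dmr(self._dmps([0.01]), self._annotation(1), min_cpgs=1)
        d = res[0]
        assert d.stouffer_p == pytest.approx(0.01, rel=1e-10)
        assert d.fisher_p == pytest.approx(0.01, rel=1e-10)

    def test_two_member_closed_forms(self):
        res = combine_dmr(self._dmps([0.05, 0.05]), self._annotation(2), min_cpgs=2)
        d = res[0]
        x2 = -2 * (2 * np.log(0.05))
        assert x2 == pytest.approx(11.9829, abs=1e-4)
        assert d.fisher_p == pytest.approx(stats.chi2.sf(x2, 4), rel=1e-10)
        z = 2 * stats.norm.isf(0.05) / np.sqrt(2)
        assert z == pytest.approx(2.3262, abs=1e-4)
        assert d.stouffer_p == pytest.approx(stats.norm.sf(z), rel=1e-10)
        assert d.stouffer_p == pytest.approx(0.0100, abs=2e-4)

    def test_region_finding_respects_gap_and_min_count(self):
        ann = ProbeAnnotation(pd.DataFrame({
            "cpg_id": [f"cg{i}" for i in range(6)],
            "chromosome": ["chr1"] * 4 + ["chr2"] * 2,
            "position": [1000, 1400, 1900, 5000, 1000, 1200],
        }))
        res = combine_dmr(self._dmps([0.5] * 6), ann, max_gap=1000, min_cpgs=3)
        assert len(res) == 1  # only the chr1 run of 3; chr2 pair too small
        assert res[0].cpg_ids == ["cg0", "cg1", "cg2"]

    def test_zero_p_clipped_and_flagged(self):
        res = combine_dmr(self._dmps([0.0, 0.01, 0.02]), self._annotation(3))
        assert res[0].clipped and np.isfinite(res[0].fisher_p)

    def test_bed_conversion_is_zero_based_half_open(self):
        res = combine_dmr(self._dmps([0.5] * 3), self._annotation(3))
        bed = dmr_to_bed(res)
        assert bed.loc[0, "chromStart"] == res[0].start - 1
        assert bed.loc[0, "chromEnd"] == res[0].end


class TestExprMethCorrelation:
    def test_perfect_negative(self):
        b = make_beta([[0.1, 0.2, 0.3, 0.4]])
        res = expr_meth_correlation(-b.values[0], b)
        assert res.loc[0, "r"] == pytest.approx(-1.0)

    def test_constructed_orthogonal_gives_zero(self):
        b = make_beta([[0.1, 0.2, 0.3]])
        res = expr_meth_correlation(np.array([1.0, -2.0, 1.0]), b)
        assert res.loc[0, "r"] == pytest.approx(0.0, abs=1e-12)

    def test_five_point_fixture_matches_covariance_formula(self, rng):
        e = rng.normal(size=5)
        b = make_beta([rng.uniform(0.1, 0.9, 5)])
        res = expr_meth_correlation(e, b)
        x, y = e, b.values[0]
        r_oracle = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert res.loc[0, "r"] == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            expr_meth_correlation(np.array([1.0, 1.0, 1.0]),
                                  make_beta([[0.1, 0.2, 0.3]]))
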