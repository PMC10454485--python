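"""Containers, beta/M conversion, QC filters and delta-beta."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bloodewas.datamodel import (
    BetaMatrix, GenotypeTable, beta_to_m, delta_beta, filter_probes,
    filter_samples, genotype_qc, hwe_chi_square, m_to_beta,
)
from conftest import make_beta


class TestBetaMConversion:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_logit2_reference_points(self, beta, m):
        out = beta_to_m(make_beta([[beta]]))
        assert out.values[0, 0] == pytest.approx(m, abs=1e-12)

    @pytest.mark.parametrize("m,beta", [(0.0, 0.5), (2.0, 0.8)])
    def test_inverse_reference_points(self, m, beta):
        mat = beta_to_m(make_beta([[0.5]]))  # template for ids
        mat.values[0, 0] = m
        assert m_to_beta(mat).values[0, 0] == pytest.approx(beta, abs=1e-12)

    def test_round_trip(self):
        b = make_beta([[0.37, 0.001, 0.999]])
        back = m_to_beta(beta_to_m(b, epsilon=1e-3))
        np.testing.assert_allclose(back.values, b.values, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1 - 1e-3))
    def test_round_trip_property(self, beta):
        b = make_beta([[beta]])
        assert abs(m_to_beta(beta_to_m(b)).values[0, 0] - beta) < 1e-10

    def test_antisymmetry(self):
        m = beta_to_m(make_beta([[0.3, 0.7]]))
        assert m.values[0, 0] == pytest.approx(-m.values[0, 1], abs=1e-12)

    def test_nonfinite_rejected_with_location(self):
        b = make_beta([[0.5, 0.4]])
        b.values[0, 1] = np.nan
        with pytest.raises(ValueError, match="s1"):
            beta_to_m(b)

    def test_epsilon_bounds_validated(self):
        with pytest.raises(ValueError):
            beta_to_m(make_beta([[0.5]]), epsilon=0.7)


class TestContainers:
    def test_beta_range_enforced(self):
        with pytest.raises(ValueError, match="out of"):
            make_beta([[1.5]])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            BetaMatrix(np.zeros((2, 1)), np.array(["a", "a"]), np.array(["s"]))

    def test_dosage_domain_enforced(self):
        with pytest.raises(ValueError, match="dosages"):
            GenotypeTable(np.array([[3.0]]), np.array(["r"]), np.array(["s"]),
                          np.array(["chr1"]), np.array([100]))


class TestProbeSampleFilters:
    def test_implanted_failures_removed_exactly(self, rng):
        b = make_beta(rng.uniform(0.2, 0.8, size=(20, 40)))
        detp = np.zeros((20, 40))
        bad = [3, 11, 17]
        detp[bad, :8] = 0.5  # fail in 20% of samples
        out, rep = filter_probes(b, detp, p_cut=0.01, max_fail_fraction=0.05)
        assert rep.removed_ids == [f"cg{i}" for i in bad]
        assert out.n_cpgs == 17

    def test_all_detected_is_identity(self, rng):
        b = make_beta(rng.uniform(0, 1, size=(5, 6)))
        out, rep = filter_probes(b, np.zeros((5, 6)))
        assert rep.removed == [] and out.n_cpgs == 5

    def test_all_probes_removed_is_an_error(self):
        b = make_beta([[0.5], [0.5]])
        with pytest.raises(ValueError, match="every probe"):
            filter_probes(b, np.ones((2, 1)), p_cut=0.01, max_fail_fraction=0.0)

    def test_sample_filter_matches_enumeration(self, rng):
        vals = rng.uniform(0, 1, size=(30, 10))
        miss = rng.random((30, 10)) < 0.08
        vals[miss] = np.nan
        b = make_beta(vals)
        out, rep = filter_samples(b, max_fail_fraction=0.1)
        expected = [f"s{j}" for j in range(10) if miss[:, j].mean() > 0.1]
        assert rep.removed_ids == expected
        assert list(out.sample_ids) == [s for s in b.sample_ids if s not in expected]

    def test_filters_idempotent(self, rng):
        vals = rng.uniform(0, 1, size=(30, 10))
        vals[rng.random((30, 10)) < 0.15] = np.nan
        once, _ = filter_samples(make_beta(vals), max_fail_fraction=0.2)
        twice, rep2 = filter_samples(once, max_fail_fraction=0.2)
        assert rep2.removed == []
        np.testing.assert_array_equal(
            np.nan_to_num(once.values, nan=-1), np.nan_to_num(twice.values, nan=-1))


class TestGenotypeQC:
    def _table(self, dosages, n_samples=None):
        d = np.asarray(dosages, dtype=float)
        n = d.shape[1]
        return GenotypeTable(
            d, np.array([f"rs{i}" for i in range(d.shape[0])], dtype=object),
            np.array([f"s{j}" for j in range(n)], dtype=object),
            np.array(["chr1"] * d.shape[0], dtype=object),
            np.arange(1, d.shape[0] + 1) * 1000,
        )

    def test_exact_hw_proportions_retained(self):
        chi2, p = hwe_chi_square(25, 50, 25)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_het_deficit_chi_square_hand_computed(self):
        # AA=50, AB=0, BB=50: p=q=0.5, expected (25,50,25), X2=25+50+25=100
        chi2, _ = hwe_chi_square(50, 0, 50)
        assert chi2 == pytest.approx(100.0, abs=1e-9)

    def test_low_call_rate_snp_removed(self, rng):
        d = rng.binomial(2, 0.3, size=(2, 100)).astype(float)
        d[0, :3] = np.nan  # 97% call rate
        g, rep = genotype_qc(self._table(d), min_snp_call=0.98, hwe_alpha=1e-20)
        assert "rs0" in [i for i, r in rep.removed] and g.n_snps == 1

    def test_hwe_failure_removed_and_monomorphic_flagged(self):
        failing = np.array([0.0] * 50 + [2.0] * 50)
        mono = np.zeros(100)
        g, rep = genotype_qc(self._table(np.vstack([failing, mono])),
                             hwe_alpha=0.05)
        assert [i for i, r in rep.removed] == ["rs0"]
        assert [i for i, r in rep.flagged] == ["rs1"]
        assert list(g.snp_ids) == ["rs1"]

    def test_hwe_decision_matches_bruteforce(self, rng):
        d = rng.binomial(2, rng.uniform(0.1, 0.9, size=30)[:, None],
                         size=(30, 200)).astype(float)
        g, rep = genotype_qc(self._table(d), hwe_alpha=0.05)
        from scipy import stats
        removed = {i for i, _ in rep.removed}
        for i in range(30):
            counts = [(d[i] == k).sum() for k in (0, 1, 2)]
            n = sum(counts)
            p = (2 * counts[0] + counts[1]) / (2 * n)
            if p in (0, 1):
                continue
            exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
            chi2 = (((np.array(counts) - exp) ** 2) / exp).sum()
            expect_removed = stats.chi2.sf(chi2, 1) < 0.05
            assert (f"rs{i}" in removed) == expect_removed


class TestDeltaBeta:
    def test_arithmetic_example(self):
        b = make_beta([[0.6, 0.8, 0.5, 0.7]])
        d = delta_beta(b, np.array([1, 1, 0, 0]))
        assert d.iloc[0] == pytest.approx(0.1)

    def test_identical_groups_zero(self):
        b = make_beta([[0.4, 0.4, 0.4, 0.4]])
        assert delta_beta(b, np.array([1, 1, 0, 0])).iloc[0] == 0.0

    def test_matches_loop_oracle_and_antisymmetry(self, rng):
        vals = rng.uniform(0, 1, size=(15, 20))
        ph = rng.integers(0, 2, size=20)
        ph[:2] = [0, 1]
        b = make_beta(vals)
        d = delta_beta(b, ph)
        for i in range(15):
            expected = vals[i][ph == 1].mean() - vals[i][ph == 0].mean()
            assert d.iloc[i] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(delta_beta(b, 1 - ph).to_numpy(),
                                   -d.to_numpy(), atol=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            delta_beta(make_beta([[0.5, 0.6]]), np.array([1, 1]))
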