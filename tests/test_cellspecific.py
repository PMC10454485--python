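"""Per-cell-type interaction model: recovery, classification, bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from bloodewas.cellspecific import (
    CsDMPResult, classify_csdmp, fit_csdmp, run_csdmp_scan, summarize_csdmp,
)
from bloodewas.datamodel import MValueMatrix, SampleMeta
from bloodewas.deconvolution import CellFractions


def _meta(pheno, rng=None):
    n = len(pheno)
    rng = rng or np.random.default_rng(0)
    return SampleMeta(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)], "phenotype": pheno,
        "age": rng.uniform(20, 60, n).round(1), "sex": rng.choice(["F", "M"], n),
        "region": ["r"] * n,
    }))


def _fractions(vals, cell_types, ids):
    return CellFractions(pd.DataFrame(vals, columns=cell_types, index=ids))


class TestFitCsdmp:
    def test_generative_interaction_recovered(self, rng):
        """M = 5 + 3*f_B*phenotype + noise: the B-cell model recovers the
        coefficient 3 within CI; the neutrophil model sees ~0."""
        n = 600
        ph = np.array([1] * 200 + [0] * 400)
        f = rng.dirichlet([12, 128], size=n)  # B small, Neu large
        m = 5 + 3 * f[:, 0] * ph + rng.normal(0, 0.1, n)
        meta = _meta(ph, rng)
        fr = _fractions(f, ["B", "Neu"], meta.sample_ids)
        res_b = fit_csdmp(m, "B", fr, meta)
        assert res_b.interaction_estimate == pytest.approx(3.0, abs=0.5)
        res_n = fit_csdmp(m, "Neu", fr, meta)
        assert abs(res_n.interaction_estimate) < 1.0

    def test_phenotype_free_m_is_null(self, rng):
        hits = 0
        for seed in range(25):
            r = np.random.default_rng(seed)
            n = 200
            ph = np.array([1] * 100 + [0] * 100)
            f = r.dirichlet([10, 90], size=n)
            m = 2 + r.normal(0, 0.5, n)
            meta = _meta(ph, r)
            fr = _fractions(f, ["B", "Neu"], meta.sample_ids)
            if fit_csdmp(m, "B", fr, meta).p > 0.05:
                hits += 1
        assert hits >= 23  # >= ~94% of seeds at the null

    def test_ten_sample_fixture_matches_normal_equations(self, rng):
        n = 10
        ph = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        f = rng.uniform(0.05, 0.3, n)
        m = rng.normal(0, 1, n)
        meta = _meta(ph, rng)
        fr = _fractions(np.column_stack([f, 1 - f]), ["B", "Neu"], meta.sample_ids)
        res = fit_csdmp(m, "B", fr, meta)
        t = meta.table
        X = np.column_stack([
            np.ones(n), f, f * ph, t["age"], (t["sex"] == "M").astype(float)])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ m)
        assert res.interaction_estimate == pytest.approx(beta_oracle[2], abs=1e-10)

    def test_label_swap_negates_estimate(self, rng):
        n = 100
        ph = np.array([1] * 50 + [0] * 50)
        f = rng.uniform(0.05, 0.3, n)
        m = 1 + 2.5 * f * ph + rng.normal(0, 0.2, n)
        fr_cols = np.column_stack([f, 1 - f])
        meta1, meta2 = _meta(ph), _meta(1 - ph)
        fr1 = _fractions(fr_cols, ["B", "Neu"], meta1.sample_ids)
        a = fit_csdmp(m, "B", fr1, meta1).interaction_estimate
        b = fit_csdmp(m, "B", fr1, meta2).interaction_estimate
        assert a == pytest.approx(-b, abs=1e-9)

    def test_zero_variance_fraction_rejected(self):
        meta = _meta(np.array([1, 0, 1, 0]))
        fr = _fractions(np.column_stack([np.full(4, 0.2), np.full(4, 0.8)]),
                        ["B", "Neu"], meta.sample_ids)
        with pytest.raises(ValueError, match="zero variance"):
            fit_csdmp(np.array([1.0, 2, 3, 4]), "B", fr, meta)


class TestClassify:
    @pytest.mark.parametrize("est,p,sig,direction", [
        (2.5, 1e-9, True, "hyper"),
        (-2.5, 1e-9, True, "hypo"),
        (1.5, 1e-12, False, "hyper"),   # fails the magnitude cut
        (2.5, 1e-6, False, "hyper"),    # fails the p cut
    ])
    def test_printed_rule(self, est, p, sig, direction):
        res = classify_csdmp(CsDMPResult("c", "B", est, p))
        assert res.significant == sig and res.direction == direction

    def test_idempotent_and_monotone(self):
        base = classify_csdmp(CsDMPResult("c", "B", 2.5, 1e-9))
        assert classify_csdmp(base) == base
        # monotone: increasing |estimate| or decreasing p never de-flags
        assert classify_csdmp(CsDMPResult("c", "B", 3.5, 1e-9)).significant
        assert classify_csdmp(CsDMPResult("c", "B", 2.5, 1e-12)).significant


class TestSummarize:
    def _df(self, entries):
        rows = []
        for cpg, ct, sig, d in entries:
            rows.append({"cpg_id": cpg, "cell_type": ct, "interaction_estimate": 0.0,
                         "p": 0.0, "direction": d, "significant": sig,
                         "estimable": True, "note": ""})
        return pd.DataFrame(rows)

    def test_set_arithmetic_example(self):
        df = self._df([
            ("a", "B", True, "hyper"), ("b", "B", True, "hyper"),
            ("c", "B", True, "hypo"),
            ("b", "Mono", True, "hyper"), ("c", "Mono", True, "hyper"),
            ("d", "Mono", True, "hypo"),
        ])
        s = summarize_csdmp(df, compare=["B", "Mono"])
        assert s["unique"]["B"] == ["a"] and s["unique"]["Mono"] == ["d"]
        assert s["shared"] == ["b", "c"]
        assert s["shared_same_direction"] == ["b"]  # c flips direction

    def test_empty_results_all_zero(self):
        df = self._df([("a", "B", False, "hyper")])
        s = summarize_csdmp(df)
        assert s["per_cell_type"]["B"]["n_csdmp"] == 0
        assert s["shared"] == []

    def test_random_fixture_matches_bruteforce_sets(self, rng):
        entries = []
        for ct in ["B", "Mono", "CD4T"]:
            for i in range(30):
                entries.append((f"c{i}", ct, bool(rng.random() < 0.4),
                                "hyper" if rng.random() < 0.5 else "hypo"))
        df = self._df(entries)
        s = summarize_csdmp(df, compare=["B", "Mono", "CD4T"])
        sets = {ct: {e[0] for e in entries if e[1] == ct and e[2]}
                for ct in ["B", "Mono", "CD4T"]}
        assert set(s["shared"]) == sets["B"] & sets["Mono"] & sets["CD4T"]
        for ct in sets:
            others = set().union(*[v for k, v in sets.items() if k != ct])
            assert set(s["unique"][ct]) == sets[ct] - others


class TestScanConsistency:
    def test_scan_matches_single_fit(self, rng):
        n = 80
        ph = np.array([1] * 40 + [0] * 40)
        meta = _meta(ph, rng)
        f = rng.dirichlet([10, 20, 70], size=n)
        fr = _fractions(f, ["B", "Mono", "Neu"], meta.sample_ids)
        vals = rng.normal(0, 1, size=(5, n))
        m = MValueMatrix(vals, np.array([f"cg{i}" for i in range(5)], dtype=object),
                         meta.sample_ids)
        scan = run_csdmp_scan(m, fr, meta, cell_types=["B", "Mono"])
        for _, row in scan.iterrows():
            i = list(m.cpg_ids).index(row["cpg_id"])
            single = fit_csdmp(vals[i], row["cell_type"], fr, meta)
            assert row["interaction_estimate"] == pytest.approx(
                single.interaction_estimate, abs=1e-10)
            assert row["p"] == pytest.approx(single.p, rel=1e-10)
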