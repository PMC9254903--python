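"""Broad-expression filter, paired signed-rank DE and dosage correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oracles import enumeration_signed_rank_p
from pandriver import expression as xp
from pandriver.io import ExpressionMatrix


def _matrix(tumour, normal=None, genes=None):
    """Build an ExpressionMatrix from gene × sample FPKM arrays."""
    tumour = np.atleast_2d(tumour)
    genes = genes or [f"G{i}" for i in range(tumour.shape[0])]
    cols, meta = [], []
    vals = []
    for j in range(tumour.shape[1]):
        cols.append(f"P{j}-T")
        meta.append({"sample_id": f"P{j}-T", "patient_id": f"P{j}",
                     "tissue": "tumour"})
    vals.append(tumour)
    if normal is not None:
        normal = np.atleast_2d(normal)
        for j in range(normal.shape[1]):
            cols.append(f"P{j}-N")
            meta.append({"sample_id": f"P{j}-N", "patient_id": f"P{j}",
                         "tissue": "normal"})
        vals.append(normal)
    values = pd.DataFrame(np.hstack(vals), index=genes, columns=cols)
    return ExpressionMatrix(values=values, sample_meta=pd.DataFrame(meta))


class TestBroadExpressionFilter:
    @pytest.mark.parametrize("n_pass, expected", [(95, True), (89, False),
                                                  (90, True)])
    def test_ninety_percent_rule_inclusive(self, n_pass, expected):
        fpkm = np.concatenate([np.full(n_pass, 2.0),
                               np.full(100 - n_pass, 0.5)])
        em = _matrix(fpkm[None, :])
        assert bool(xp.broad_expression_filter(em).iloc[0]) is expected


class TestSignedRank:
    def test_all_zero_differences_vacuous(self):
        w, p, n = xp.signed_rank_test(np.zeros(8))
        assert p == 1.0 and n == 0

    def test_tied_example_matches_enumeration(self):
        d = np.array([1, 2, 3, 4, 5, -1.0])
        _, p, _ = xp.signed_rank_test(d)
        assert p == pytest.approx(enumeration_signed_rank_p(d))
        assert p == pytest.approx(0.09375)

    def test_matches_enumeration_oracle_random_vectors(self, rng):
        for _ in range(100):
            n = rng.integers(3, 11)
            d = np.round(rng.normal(0.2, 1.0, n), 2)
            _, p, _ = xp.signed_rank_test(d)
            assert p == pytest.approx(enumeration_signed_rank_p(d), abs=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(-5, 5, allow_nan=False).map(lambda v: round(v, 1)),
                    min_size=3, max_size=10))
    def test_agrees_with_enumeration_property(self, diffs):
        d = np.array(diffs)
        _, p, _ = xp.signed_rank_test(d)
        assert p == pytest.approx(enumeration_signed_rank_p(d), abs=1e-12)

    def test_large_n_matches_scipy_normal_approximation(self, rng):
        d = rng.normal(0.1, 1.0, 40)
        _, p, _ = xp.signed_rank_test(d)
        ref = stats.wilcoxon(d, method="approx", correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-10)


class TestPairedWilcoxonDe:
    def test_identical_pairs_no_flag(self):
        fpkm = np.tile(np.linspace(1, 5, 12), (3, 1))
        em = _matrix(fpkm, fpkm)
        out = xp.paired_wilcoxon_de(em, "X")
        assert (out["p"] == 1.0).all()
        assert not out["de_flag"].any()

    def test_planted_upregulation_detected(self, rng):
        n_genes, n_pairs = 40, 30
        base = rng.lognormal(1.5, 0.4, (n_genes, n_pairs))
        tum = base.copy()
        tum[0] *= 2 ** 1.5   # delta = 1.5 log2 units on gene 0
        tum *= rng.lognormal(0, 0.2, tum.shape)
        nor = base * rng.lognormal(0, 0.2, base.shape)
        em = _matrix(tum, nor)
        out = xp.paired_wilcoxon_de(em, "X").set_index("gene_id")
        assert bool(out.loc["G0", "de_flag"])
        assert out.loc["G0", "direction"] == "up"

    def test_insufficient_pairs_reported(self):
        em = _matrix(np.ones((2, 12)) * 3, np.ones((2, 4)) * 2)
        out = xp.paired_wilcoxon_de(em, "X", min_pairs=10)
        assert not out["de_flag"].any()
        assert (out["reason"] == "insufficient pairs").all()

    def test_no_normals_reported(self):
        em = _matrix(np.ones((2, 12)) * 3)
        out = xp.paired_wilcoxon_de(em, "X")
        assert (out["reason"] == "no matched normals").all()


class TestExprCnvCorrelation:
    def _em_cn(self, expr_log2, cn):
        # FPKM chosen so that log2(FPKM + 1) equals expr_log2 exactly
        fpkm = 2.0 ** np.atleast_2d(expr_log2) - 1.0
        em = _matrix(np.clip(fpkm, 0, None))
        cn_df = pd.DataFrame(np.atleast_2d(cn), index=em.values.index,
                             columns=em.values.columns)
        return em, cn_df

    def test_perfect_linear_dosage_r_one(self):
        cn = np.array([0.0, 0.5, 1.0, 1.5])
        em, cn_df = self._em_cn(1 + 2 * cn, cn)
        out = xp.expr_cnv_correlation(em, cn_df, "X", fraction=0.5)
        assert out["r"].iat[0] == pytest.approx(1.0)
        assert bool(out["correlated"].iat[0])

    def test_four_point_example_matches_scipy(self):
        x = np.array([0, 0.5, 1.0, 1.5])
        y_log2 = np.array([1.0, 2.0, 3.0, 4.0])
        em, cn_df = self._em_cn(y_log2, x)
        out = xp.expr_cnv_correlation(em, cn_df, "X", fraction=0.0)
        expr = np.log2(em.values.to_numpy()[0] + 1.0)
        r_ref, p_ref = stats.pearsonr(x, expr)
        assert out["r"].iat[0] == pytest.approx(r_ref, abs=1e-9)
        assert out["p"].iat[0] == pytest.approx(p_ref, abs=1e-9)

    def test_vectorized_matches_scipy_on_random_data(self, rng):
        n = 30
        cn = rng.normal(0, 0.4, (5, n))
        expr = 2.0 ** (3 + 0.8 * cn + rng.normal(0, 0.5, (5, n)))
        em = _matrix(expr)
        cn_df = pd.DataFrame(cn, index=em.values.index,
                             columns=em.values.columns)
        out = xp.expr_cnv_correlation(em, cn_df, "X", fraction=0.0)
        for i in range(5):
            r_ref, p_ref = stats.pearsonr(cn[i], np.log2(expr[i] + 1))
            assert out["r"].iat[i] == pytest.approx(r_ref, abs=1e-9)
            assert out["p"].iat[i] == pytest.approx(p_ref, rel=1e-6)

    def test_zero_variance_reported_not_correlated(self):
        cn = np.zeros(10)
        em, cn_df = self._em_cn(np.linspace(1, 3, 10), cn)
        out = xp.expr_cnv_correlation(em, cn_df, "X", fraction=0.0)
        assert not out["correlated"].iat[0]
        assert out["reason"].iat[0] == "zero variance"

    def test_affine_rescaling_invariance(self, rng):
        n = 25
        cn = rng.normal(0, 0.5, n)
        expr = 2.0 ** (2 + cn + rng.normal(0, 0.3, n))
        em1, cn1 = self._em_cn(np.log2(expr + 1), cn)
        em2, cn2 = self._em_cn(np.log2(expr + 1), 3 * cn + 5)
        r1 = xp.expr_cnv_correlation(em1, cn1, "X", fraction=0.0)["r"].iat[0]
        r2 = xp.expr_cnv_correlation(em2, cn2, "X", fraction=0.0)["r"].iat[0]
        assert r1 == pytest.approx(r2, abs=1e-9)
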