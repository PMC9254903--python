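"""Gene-level copy-number mapping, G-scores, permutation q-values, flags."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pandriver import io as omio
from pandriver import scna


def _seg(sample, chrom, start, end, val):
    return {"sample_id": sample, "chrom": chrom, "start": start, "end": end,
            "n_markers": 1, "log2_ratio": val}


class TestSegmentsToGeneMatrix:
    def test_gene_inside_single_segment(self, tiny_gene_model):
        segs = pd.DataFrame([_seg("S1", "1", 1, 5000, 0.5)])
        m = scna.segments_to_gene_matrix(segs, tiny_gene_model)
        assert m.values.loc["G1", "S1"] == pytest.approx(0.5)

    def test_length_weighted_split(self, tiny_gene_model):
        # G1 spans 100-199; 60 bases in the 0.5 segment, 40 in the 0.0 one
        segs = pd.DataFrame([_seg("S1", "1", 1, 159, 0.5),
                             _seg("S1", "1", 160, 5000, 0.0)])
        m = scna.segments_to_gene_matrix(segs, tiny_gene_model)
        assert m.values.loc["G1", "S1"] == pytest.approx(0.30)

    def test_all_zero_segments_give_zero_matrix(self, tiny_gene_model):
        segs = pd.DataFrame([_seg("S1", "1", 1, 5000, 0.0),
                             _seg("S1", "2", 1, 5000, 0.0)])
        m = scna.segments_to_gene_matrix(segs, tiny_gene_model)
        assert (m.values.to_numpy() == 0).all()

    def test_uncovered_gene_imputed_zero_and_flagged(self, tiny_gene_model):
        segs = pd.DataFrame([_seg("S1", "1", 1, 5000, 0.4)])  # chr2 absent
        m = scna.segments_to_gene_matrix(segs, tiny_gene_model)
        assert m.values.loc["G3", "S1"] == 0.0
        assert bool(m.imputed.loc["G3", "S1"])
        assert not bool(m.imputed.loc["G1", "S1"])


class TestGscore:
    def test_hand_computed_amplification(self):
        x = np.zeros((1, 10))
        x[0, :4] = 0.5
        m = pd.DataFrame(x, index=["G"], columns=[f"S{i}" for i in range(10)])
        assert scna.gscore(m, "amp", 0.1)["G"] == pytest.approx(0.16)

    def test_hand_computed_deletion(self):
        x = np.zeros((1, 10))
        x[0, :5] = -0.6
        m = pd.DataFrame(x, index=["G"], columns=[f"S{i}" for i in range(10)])
        assert scna.gscore(m, "del", 0.1)["G"] == pytest.approx(0.25)
        assert scna.gscore(m, "amp", 0.1)["G"] == 0.0

    def test_zero_matrix_gives_zero_scores(self):
        m = pd.DataFrame(np.zeros((3, 4)))
        assert (scna.gscore(m, "amp").to_numpy() == 0).all()
        assert (scna.gscore(m, "del").to_numpy() == 0).all()

    def test_no_samples_is_an_error(self):
        with pytest.raises(ValueError):
            scna.gscore(pd.DataFrame(index=["G"]), "amp")

    def test_invariant_to_sample_and_gene_order(self, rng):
        x = rng.normal(0, 0.3, (6, 8))
        m = pd.DataFrame(x, index=list("ABCDEF"))
        g1 = scna.gscore(m, "amp")
        perm = m.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2)
        g2 = scna.gscore(perm, "amp")
        pd.testing.assert_series_equal(g1.sort_index(), g2.sort_index(),
                                       check_names=False)

    def test_monotone_in_amplitude(self, rng):
        x = rng.normal(0, 0.3, (6, 8))
        m = pd.DataFrame(x)
        boosted = m.where(m <= 0.1, m * 2)
        g1, g2 = scna.gscore(m, "amp"), scna.gscore(boosted, "amp")
        affected = (m > 0.1).any(axis=1)
        assert (g2[affected] > g1[affected]).all()
        assert (g2[~affected] == g1[~affected]).all()


class TestGscoreQvalues:
    def test_zero_score_gives_p_and_q_one(self, rng):
        x = rng.normal(0, 0.02, (20, 10))
        x[0] = 0.0
        m = pd.DataFrame(x)
        p, q = scna.gscore_qvalues(m, "amp", n_perm=200, seed=1)
        g = scna.gscore(m, "amp")
        assert p[g == 0].eq(1.0).all()
        assert q[g == 0].eq(1.0).all()

    def test_constant_matrix_all_q_one(self):
        m = pd.DataFrame(np.zeros((5, 6)))
        _, q = scna.gscore_qvalues(m, "amp", n_perm=100, seed=0)
        assert q.eq(1.0).all()

    def test_q_monotone_in_observed_g(self, rng):
        x = rng.normal(0, 0.2, (30, 12))
        m = pd.DataFrame(x)
        g = scna.gscore(m, "amp")
        _, q = scna.gscore_qvalues(m, "amp", n_perm=300, seed=5)
        order = np.argsort(-g.to_numpy())
        assert (np.diff(q.to_numpy()[order]) >= -1e-12).all()

    def test_matches_exact_pooled_null_on_small_matrix(self, rng):
        """The pooled permutation null factorizes over samples: each sample
        contributes a uniform draw from its own contribution values, so the
        exact per-gene null tail is a full g^n enumeration."""
        x = rng.normal(0, 0.4, (5, 4))
        m = pd.DataFrame(x, index=list("ABCDE"))
        theta = 0.1
        contrib = np.maximum(0.0, x - theta)
        exact_null = np.array([
            sum(combo) / 4.0
            for combo in itertools.product(*[contrib[:, s] for s in range(4)])
        ])
        g_obs = scna.gscore(m, "amp", theta)
        p_mc, _ = scna.gscore_qvalues(m, "amp", n_perm=4000, seed=9)
        for gene, g in g_obs.items():
            p_exact = (exact_null >= g - 1e-12).mean()
            assert p_mc[gene] == pytest.approx(p_exact, abs=0.03)


class TestFlagsAndPanCancer:
    def test_threshold_combinations(self):
        df = pd.DataFrame({
            "gene_id": ["A", "B", "C"], "cancer_type": "X",
            "g_amp": [0.16, 0.09, 0.5], "q_amp": [0.01, 0.001, 0.3],
            "g_del": [0.0, 0.0, 0.0], "q_del": [1.0, 1.0, 1.0],
        })
        out = scna.flag_recurrent(df)
        assert out["recurrent_amp"].to_list() == [True, False, False]
        assert out["scna_flag"].to_list() == [True, False, False]

    def test_pan_cancer_sum_and_order_invariance(self):
        rows = []
        for ct, g in zip("XYZ", [0.2, 0.3, 0.0]):
            rows.append({"gene_id": "A", "cancer_type": ct,
                         "g_amp": g, "g_del": 0.0,
                         "q_amp": 1.0, "q_del": 1.0})
        df = pd.DataFrame(rows)
        pan = scna.pan_cancer_gscore(df)
        amp = pan[pan["direction"] == "amp"].set_index("gene_id")["pan_g"]
        assert amp["A"] == pytest.approx(0.5)
        pan2 = scna.pan_cancer_gscore(df.iloc[::-1].reset_index(drop=True))
        amp2 = pan2[pan2["direction"] == "amp"].set_index("gene_id")["pan_g"]
        assert amp2["A"] == pytest.approx(amp["A"])

    def test_single_cancer_identity(self):
        df = pd.DataFrame([{"gene_id": "A", "cancer_type": "X",
                            "g_amp": 0.42, "g_del": 0.1,
                            "q_amp": 1.0, "q_del": 1.0}])
        pan = scna.pan_cancer_gscore(df)
        assert pan.set_index(["gene_id", "direction"]).loc[
            ("A", "amp"), "pan_g"] == pytest.approx(0.42)


class TestIngestExternal:
    def test_threshold_application_and_in_peak(self):
        t = pd.DataFrame([
            {"gene_id": "CHD7", "cancer_type": "COADREAD", "direction": "amp",
             "g": 0.4, "q": 0.01, "in_peak": True},
            {"gene_id": "CHD5", "cancer_type": "COADREAD", "direction": "del",
             "g": 0.4, "q": 0.01, "in_peak": False},
        ])
        out = scna.ingest_external_scna(t).set_index("gene_id")
        assert bool(out.loc["CHD7", "recurrent_amp"])
        assert not bool(out.loc["CHD5", "recurrent_del"])  # in_peak overrides

    def test_missing_q_column_error_names_column(self):
        t = pd.DataFrame([{"gene_id": "A", "cancer_type": "X",
                           "direction": "amp", "g": 0.4}])
        with pytest.raises(omio.FormatError, match="q"):
            scna.ingest_external_scna(t)
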