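"""The synthetic cohort generator: determinism, planted effects, validity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pandriver as pdv
from pandriver import synth


class TestConfig:
    def test_infeasible_fusion_plant_rejected(self):
        cfg = pdv.default_config(
            n_cancer_types=1, n_tumour=3, n_normal_pairs=0,
            planted={"CT01": {"CHD7": ("fusion",)}})
        with pytest.raises(ValueError, match="fusion"):
            cfg.validate()

    def test_unknown_planted_gene_rejected(self):
        cfg = pdv.default_config(
            n_cancer_types=1, planted={"CT01": {"NOPE": ("mutation",)}})
        with pytest.raises(ValueError, match="NOPE"):
            cfg.validate()

    def test_more_normals_than_tumours_rejected(self):
        cfg = pdv.default_config(n_cancer_types=1, n_tumour=5,
                                 n_normal_pairs=6)
        with pytest.raises(ValueError):
            cfg.validate()


class TestDeterminism:
    def test_identical_seed_identical_cohort(self):
        cfg = pdv.default_config(n_cancer_types=2, n_tumour=30,
                                 n_normal_pairs=10, n_decoys=20,
                                 planted={"CT01": {"CHD7": ("scna_amp",
                                                            "mutation")}})
        b1, t1 = pdv.simulate_cohort(cfg, 7)
        b2, t2 = pdv.simulate_cohort(cfg, 7)
        for ct in b1:
            pd.testing.assert_frame_equal(b1[ct].segments, b2[ct].segments)
            pd.testing.assert_frame_equal(b1[ct].mutations, b2[ct].mutations)
            pd.testing.assert_frame_equal(b1[ct].expression.values,
                                          b2[ct].expression.values)
            pd.testing.assert_frame_equal(b1[ct].clinical, b2[ct].clinical)
        assert t1.as_dict() == t2.as_dict()

    def test_different_seed_differs(self):
        cfg = pdv.default_config(n_cancer_types=1, n_tumour=20,
                                 n_normal_pairs=5, n_decoys=10)
        b1, _ = pdv.simulate_cohort(cfg, 1)
        b2, _ = pdv.simulate_cohort(cfg, 2)
        assert not b1["CT01"].segments.equals(b2["CT01"].segments)

    def test_write_cohort_byte_identical(self, tmp_path):
        cfg = pdv.default_config(n_cancer_types=1, n_tumour=15,
                                 n_normal_pairs=5, n_decoys=10)
        for d in ("a", "b"):
            bundles, truth = pdv.simulate_cohort(cfg, 3)
            pdv.write_cohort(bundles, truth, tmp_path / d)
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == twin.read_bytes(), f.name


class TestPlantedEffects:
    def test_null_config_background_only(self):
        cfg = pdv.default_config(n_cancer_types=1, n_tumour=40,
                                 n_normal_pairs=10, n_decoys=30)
        bundles, truth = pdv.null_cohort(cfg, 5)
        assert truth.planted_drivers == {"CT01": {}}
        seg = bundles["CT01"].segments
        # pure Normal(0, 0.05) background: amplitudes far below focal scale
        assert seg["log2_ratio"].abs().max() < 0.3

    def test_carrier_fraction_within_binomial_bounds(self):
        """f = 0.4, N = 200: the planted-carrier count must sit inside the
        central 99% binomial interval (12 independent cohorts checked)."""
        lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.4)
        carriers = []
        for seed in range(12):
            cfg = pdv.default_config(
                n_cancer_types=1, n_tumour=200, n_normal_pairs=0,
                n_decoys=20, planted={"CT01": {"CHD7": ("scna_amp",)}})
            bundles, _ = pdv.simulate_cohort(cfg, seed)
            seg = bundles["CT01"].segments
            focal = seg[(seg["log2_ratio"] > 0.3)
                        & ((seg["end"] - seg["start"]) < 6_000_000)]
            carriers.append(focal["sample_id"].nunique())
        assert all(lo <= c <= hi for c in carriers), carriers

    def test_mutation_driver_rate_elevated(self):
        cfg = pdv.default_config(
            n_cancer_types=1, n_tumour=400, n_normal_pairs=0, n_decoys=100,
            planted={"CT01": {"CHD7": ("mutation",)}})
        bundles, _ = pdv.simulate_cohort(cfg, 11)
        muts = bundles["CT01"].mutations.drop_duplicates(["sample_id", "gene_id"])
        freq = muts.groupby("gene_id").size() / 400
        assert freq.get("CHD7", 0) > 0.04          # ~8% planted
        decoys = freq[freq.index.str.startswith("DECOY")]
        assert decoys.max() < 0.05                 # ~1% background

    def test_dosage_coupling_present(self):
        """Expression tracks planted copy number through the dosage slope."""
        cfg = pdv.default_config(
            n_cancer_types=1, n_tumour=150, n_normal_pairs=0, n_decoys=10,
            planted={"CT01": {"CHD7": ("scna_amp",)}})
        bundles, _ = pdv.simulate_cohort(cfg, 13)
        b = bundles["CT01"]
        cn = pdv.segments_to_gene_matrix(b.segments, b.gene_model).values
        expr = np.log2(b.expression.values.loc["CHD7",
                                               b.tumour_samples] + 1)
        r, p = stats.pearsonr(cn.loc["CHD7", b.tumour_samples], expr)
        # expected r ~ beta_cn*sd(cn)/sqrt((beta_cn*sd(cn))^2 + sigma^2) ~ 0.45
        assert r > 0.3 and p < 1e-6

    def test_null_survival_p_uniform(self):
        """theta = 0: Wald p-values across >= 200 genes look uniform (KS)."""
        cfg = pdv.default_config(n_cancer_types=1, n_tumour=300,
                                 n_normal_pairs=0, n_decoys=200)
        bundles, _ = pdv.null_cohort(cfg, 17)
        b = bundles["CT01"]
        out = pdv.survival_results(b.expression, b.clinical, "CT01")
        ks = stats.kstest(out["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_event_fraction_reasonable(self):
        cfg = pdv.default_config(n_cancer_types=1, n_tumour=300,
                                 n_normal_pairs=0, n_decoys=10)
        bundles, _ = pdv.null_cohort(cfg, 19)
        ev = bundles["CT01"].clinical["os_event"].mean()
        assert 0.3 < ev < 0.8


class TestBundleValidity:
    def test_all_layers_pass_io_validation(self, planted_two_cancer, cohort_dir):
        """Round-tripping the written cohort re-validates every table with
        zero repairs."""
        from pandriver import pipeline as pl
        bundles, reports = pl.load_cohorts(cohort_dir)
        for ct, rep in reports.items():
            for layer, r in rep.items():
                assert r["rows_dropped"] == 0, (ct, layer)
                assert r["repairs"] == 0, (ct, layer)
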