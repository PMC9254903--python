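import numpy as np
import pandas as pd
import pytest

import pandriver as pdv


@pytest.fixture(scope="session")
def planted_two_cancer():
    """Two-cancer simulation with multi-channel planted drivers."""
    planted = {
        "CT01": {"CHD7": ("scna_amp", "mutation", "fusion", "de_up"),
                 "HELLS": ("scna_del", "prognosis", "de_up")},
        "CT02": {"CHD7": ("scna_amp", "de_up", "prognosis")},
    }
    cfg = pdv.default_config(n_cancer_types=2, n_tumour=80,
                             n_normal_pairs=25, n_decoys=50, planted=planted)
    bundles, truth = pdv.simulate_cohort(cfg, seed=42)
    return cfg, bundles, truth


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, planted_two_cancer):
    _, bundles, truth = planted_two_cancer
    d = tmp_path_factory.mktemp("cohort")
    pdv.write_cohort(bundles, truth, d)
    return d


@pytest.fixture()
def tiny_gene_model():
    return pd.DataFrame({
        "gene_id": ["G1", "G2", "G3"],
        "chrom": ["1", "1", "2"],
        "start": [100, 1000, 500],
        "end": [199, 1999, 999],
        "strand": ["+", "-", "+"],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
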