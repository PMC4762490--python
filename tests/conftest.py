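import numpy as np
import pandas as pd
import pytest

from cervidct import FeatureTable, load_moments, simulate_cohort


@pytest.fixture(scope="session")
def modern_moments():
    return load_moments("modern")


@pytest.fixture(scope="session")
def archaeological_moments():
    return load_moments("archaeological")


@pytest.fixture(scope="session")
def modern_cohort(modern_moments):
    """One simulated modern corpus: 17 red deer + 22 reindeer."""
    return simulate_cohort(modern_moments, seed=1234)


@pytest.fixture
def toy_table():
    """Tiny hand-built feature table with both species."""
    rows = []
    rng = np.random.default_rng(7)
    for i in range(4):
        rows.append({
            "sample_id": f"rd{i}", "species": "red_deer", "corpus": "modern",
            "anatomical_location": "", "bv_tv": 63 + rng.normal(0, 2),
            "tb_n": 2.8 + rng.normal(0, 0.1), "tb_th": 0.23, "tb_sp": 0.24,
            "tb_pf": -10.5, "smi": -2.8,
        })
        rows.append({
            "sample_id": f"re{i}", "species": "reindeer", "corpus": "modern",
            "anatomical_location": "", "bv_tv": 65 + rng.normal(0, 2),
            "tb_n": 3.5 + rng.normal(0, 0.1), "tb_th": 0.19, "tb_sp": 0.18,
            "tb_pf": -14.3, "smi": -3.0,
        })
    return FeatureTable(pd.DataFrame.from_records(rows))


def separable_table(n_per_class=10, gap=30.0, seed=0):
    """Two far-apart Gaussian blobs in biomarker space."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp, offset in (("red_deer", 0.0), ("reindeer", gap)):
        for i in range(n_per_class):
            x = rng.normal(offset, 1.0, size=6)
            rows.append({
                "sample_id": f"{sp}_{i}", "species": sp, "corpus": "synthetic",
                "anatomical_location": "",
                "bv_tv": abs(x[0]) + 30, "tb_n": abs(x[1]), "tb_th": abs(x[2]),
                "tb_sp": abs(x[3]), "tb_pf": x[4], "smi": x[5],
            })
    return FeatureTable(pd.DataFrame.from_records(rows))
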