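import numpy as np
import pandas as pd
import pytest

from crossregen import CountMatrix, SimConfig, simulate_paired_cohort, simulate_timecourse


def make_counts(values, genes=None, samples=None, conditions=None, **meta_cols):
    """Small CountMatrix from a nested list."""
    arr = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    conditions = conditions or ["healthy"] * arr.shape[1]
    meta = pd.DataFrame({"condition": conditions, **meta_cols}, index=pd.Index(samples))
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples), meta)


def paired_counts(tumor, normal, genes=None):
    """CountMatrix with one tumor/normal pair per column pair."""
    tumor, normal = np.asarray(tumor), np.asarray(normal)
    n = tumor.shape[1]
    counts = np.concatenate([tumor, normal], axis=1)
    samples = [f"t{i}" for i in range(n)] + [f"n{i}" for i in range(n)]
    genes = genes or [f"g{i}" for i in range(tumor.shape[0])]
    meta = pd.DataFrame(
        {
            "condition": ["tumor"] * n + ["normal"] * n,
            "pair_id": [f"p{i}" for i in range(n)] * 2,
        },
        index=pd.Index(samples),
    )
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest planted cohort shared by read-only tests."""
    cfg = SimConfig(seed=42, n_genes=1200, n_pairs=10, frac_de=0.15)
    cm, cm_mi, truth = simulate_paired_cohort(cfg)
    return cfg, cm, cm_mi, truth


@pytest.fixture(scope="session")
def small_timecourse():
    cfg = SimConfig(seed=7, n_genes=1000, frac_de=0.3)
    cm, truth = simulate_timecourse(cfg)
    return cfg, cm, truth
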