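import numpy as np
import pandas as pd
import pytest

from methccanet import BetaMatrix, ClinicalTable, PipelineConfig, SyntheticConfig
from methccanet.synthetic import generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic cohort shared by read-only tests."""
    return generate_dataset(SyntheticConfig(), seed=0)


@pytest.fixture(scope="session")
def synthetic_pipeline_config():
    """Pipeline settings matched to the synthetic cohort's scale (30-gene
    modules cannot survive the published 100-gene filter)."""
    return PipelineConfig(min_module_size=10)


@pytest.fixture()
def tiny_beta():
    """3 sites x 4 samples, plain values."""
    return BetaMatrix(
        pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4], [0.5, 0.6, 0.7, 0.8], [0.2, 0.4, 0.6, 0.8]],
            index=["cg1", "cg2", "cg3"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


def make_clinical(sample_ids, groups=None, **overrides) -> ClinicalTable:
    n = len(sample_ids)
    rng = np.random.default_rng(7)
    data = {
        "group": groups if groups is not None else ["case"] * n,
        "event": rng.binomial(1, 0.7, n),
        "time": rng.exponential(500.0, n).round(1),
        "age": rng.normal(65, 8, n).round(1),
        "stage_T": rng.choice([1, 2, 3, 4], n),
        "stage_N": rng.choice([0, 1, 2], n),
        "stage_M": rng.binomial(1, 0.2, n),
    }
    data.update(overrides)
    return ClinicalTable(pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")))
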