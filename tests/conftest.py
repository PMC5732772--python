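import numpy as np
import pandas as pd
import pytest

from uratemr import DEFAULT_WEIGHTS
from uratemr.synthetic import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def weights():
    """The four urate-transporter instrument SNPs with oriented weights."""
    return list(DEFAULT_WEIGHTS)


@pytest.fixture(scope="session")
def default_params():
    return SimParams()


@pytest.fixture(scope="session")
def cohort(default_params):
    """One default synthetic cohort (n = 3,753), shared read-only."""
    return simulate_cohort(default_params, seed=20240101)


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """A cheaper cohort for structural (non-statistical) checks."""
    from dataclasses import replace

    return simulate_cohort(replace(default_params, n=400), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def pheno_frame():
    """Hand-written phenotype table for io tests."""
    return pd.DataFrame(
        {
            "subject_id": ["A", "B", "C", "D"],
            "age": [60.0, 70.0, 65.0, 72.0],
            "sex": ["male", "F", "female", "M"],
            "bmi": [24.0, 26.0, 22.5, 25.0],
            "fbg": [5.5, 6.0, 5.2, 5.8],
            "bun": [5.0, 6.1, 4.8, 5.5],
            "su": [350.0, 420.0, 300.0, 500.0],
            "tbil": [18.0, 21.0, 15.0, 25.0],
            "urate_lowering_drug": [0, 0, 0, 0],
        }
    )


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
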