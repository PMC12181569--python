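import numpy as np
import pandas as pd
import pytest

from senscan import ExpressionMatrix, SyntheticTruth, default_signature, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-sample, 3-dataset cohort with injected duplicates and QC
    outliers, shared across read-only tests."""
    truth = SyntheticTruth(
        seed=7, n_samples=150, n_datasets=3, n_duplicates=4, n_qc_outliers=2
    )
    matrix, clinical, qc, truth = generate_cohort(truth)
    return matrix, clinical, qc, truth


@pytest.fixture(scope="session")
def signature():
    return default_signature()


def toy_matrix(values, shared=None, dataset="DS01", platform="GPL96"):
    """Small ExpressionMatrix from a dict/DataFrame of probe -> intensities."""
    df = pd.DataFrame(values, dtype=float)
    return ExpressionMatrix(
        values=df,
        dataset_of=pd.Series(dataset, index=df.columns),
        platform_of=pd.Series(platform, index=df.columns),
        shared_probes=pd.Index(shared if shared is not None else df.index),
    )


def random_survival(rng, n, event_rate=0.6, decimals=1):
    """Random right-censored survival data with ties (month resolution)."""
    times = np.round(rng.exponential(20.0, n), decimals) + 0.5
    events = (rng.random(n) < event_rate).astype(int)
    return times, events
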