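import numpy as np
import pandas as pd
import pytest

import microhi as mh


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def tiny_table():
    frame = pd.DataFrame(
        {"s1": [0.5, 0.3, 0.2], "s2": [0.2, 0.2, 0.6]},
        index=["TaxA", "TaxB", "TaxC"],
    )
    return mh.AbundanceTable(frame)


@pytest.fixture
def tiny_pmap():
    frame = pd.DataFrame(
        {
            "pathogenic": [1.0, 0.0, 0.0],
            "mobile": [0.0, 1.0, 0.0],
            "stress": [0.0, 0.0, 0.0],
        },
        index=["TaxA", "TaxB", "TaxC"],
    )
    return mh.PhenotypeMap(frame)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (read-only)."""
    return mh.simulate_dataset(mh.default_params(), seed=0)


@pytest.fixture(scope="session")
def cohort_meta(default_cohort):
    return mh.metadata_frame(default_cohort.metadata)


@pytest.fixture(scope="session")
def cohort_truth(default_cohort):
    return pd.Series(default_cohort.truth.status)


def random_table(rng, n_taxa, n_samples):
    counts = rng.random((n_taxa, n_samples)) + 1e-3
    frame = pd.DataFrame(
        counts,
        index=[f"t{i}" for i in range(n_taxa)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return mh.AbundanceTable.from_dataframe(frame)
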