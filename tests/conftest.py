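import numpy as np
import pandas as pd
import pytest

from ditchnet import synth


@pytest.fixture(scope="session")
def default_params():
    return synth.default_community_params()


@pytest.fixture(scope="session")
def design36():
    return synth.generate_design(1)


@pytest.fixture(scope="session")
def table36(default_params, design36):
    return synth.sample_community(default_params, design36, seed=11)


def make_table(counts: np.ndarray, treatments=None, periods=None, taxa=None):
    """Small hand-built AbundanceTable for metric/network unit tests."""
    counts = np.asarray(counts)
    n = counts.shape[0]
    taxa = taxa or [f"t{j}" for j in range(counts.shape[1])]
    treatments = treatments if treatments is not None else [0.0] * n
    periods = periods or ["after"] * n
    ditches = [f"D{i:02d}" for i in range(n)]
    idx = [f"{d}:{p}" for d, p in zip(ditches, periods)]
    meta = pd.DataFrame(
        {
            "ditch_id": ditches,
            "block": [f"B{i % 3}" for i in range(n)],
            "treatment_ugL": treatments,
            "period": periods,
        },
        index=idx,
    )
    return synth.AbundanceTable(pd.DataFrame(counts, index=idx, columns=taxa), meta)
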