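import numpy as np
import pandas as pd
import pytest

from olfsel.synth import CountSimSpec, gen_counts


@pytest.fixture(scope="session")
def null_counts_small():
    """A small null NB count matrix (no planted effects), shared across tests."""
    spec = CountSimSpec(n_genes=400, samples_per_group=4, dispersion=0.1,
                        n_de=0, lib_size_range=(200_000, 300_000), seed=101)
    return gen_counts(spec)


@pytest.fixture()
def toy_counts():
    """Tiny deterministic count matrix with equal library sizes."""
    genes = [f"g{i}" for i in range(4)]
    data = {
        "s1": [10, 100, 40, 850],
        "s2": [12, 98, 41, 849],
        "s3": [9, 103, 38, 850],
        "s4": [11, 99, 42, 848],
    }
    return pd.DataFrame(data, index=genes)
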