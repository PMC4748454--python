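import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirnaome.mirna_mapper import MatureReference
from mirnaome.synthetic_data import make_reference

settings.register_profile("default", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_reference() -> MatureReference:
    """20 random mature miRNAs, 18-25 nt, pairwise Hamming >= 3 at equal length."""
    return make_reference(20, (18, 25), rng_seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def toy_counts():
    """Small hand-checkable count matrix over 4 samples."""
    from mirnaome.mirna_mapper import CountMatrix

    counts = pd.DataFrame(
        {
            "s1": [50, 9, 4, 0, 12],
            "s2": [30, 0, 3, 0, 0],
            "s3": [20, 0, 3, 2, 0],
            "s4": [10, 0, 0, 0, 0],
        },
        index=[f"m{i}" for i in range(1, 6)],
    )
    return CountMatrix(counts)
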