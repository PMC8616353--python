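import warnings

import numpy as np
import pandas as pd
import pytest

from glycotraits.library import default_library
from glycotraits.synthetic_cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def library_by_id(library):
    return {r.column_id: r for r in library}


@pytest.fixture(scope="session")
def small_cohort():
    """Default 21-sample cohort, deterministic."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(CohortConfig(seed=42))


def random_fractional_matrix(library, rng, n_samples=4):
    """Random per-class-closed fractional abundance matrix over the library."""
    cols = [r.column_id for r in library]
    out = pd.DataFrame(0.0, index=[f"s{i}" for i in range(n_samples)], columns=cols)
    for cls in ("N", "O"):
        sub = [c for c in cols if c.startswith(cls + ":")]
        raw = rng.gamma(0.5, size=(n_samples, len(sub)))
        out[sub] = raw / raw.sum(axis=1, keepdims=True) * 100.0
    return out
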