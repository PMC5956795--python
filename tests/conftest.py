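import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240516)


@pytest.fixture
def small_matrix():
    """6 genes x 24 samples, two groups of 12, with one correlated pair."""
    r = np.random.default_rng(7)
    n = 24
    vals = r.normal(size=(6, n))
    vals[1] = vals[0] + 0.1 * r.normal(size=n)  # g1 tracks g0 in both groups
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(n)]
    values = pd.DataFrame(vals, index=genes, columns=samples)
    groups = pd.Series(["A"] * 12 + ["B"] * 12, index=samples)
    from dcenet.preprocess import ExpressionMatrix

    return ExpressionMatrix(values, groups)
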