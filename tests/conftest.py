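import numpy as np
import pandas as pd
import pytest

from gctmir.io_core import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_matrix():
    """4 features x 6 samples, two groups, hand-constructed values."""
    data = pd.DataFrame(
        [[5.0, 5.0, 5.0, 1.0, 1.0, 1.0],
         [2.0, 2.5, 1.5, 2.0, 2.5, 1.5],
         [0.0, 0.5, 1.0, 3.0, 3.5, 4.0],
         [7.0, 7.0, 7.0, 7.0, 7.0, 7.0]],
        index=["up_a", "flat", "up_b", "constant"],
        columns=["a1", "a2", "a3", "b1", "b2", "b3"],
    )
    groups = {s: ("A" if s.startswith("a") else "B") for s in data.columns}
    return ExpressionMatrix(data, groups)
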