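import numpy as np
import pandas as pd
import pytest

from moltset.de_stats import StageDesign
from moltset.matrix import ExpressionMatrix


@pytest.fixture
def two_group_matrix():
    """One feature, A=(1,2,3) vs B=(3,4,5): the hand-worked ANOVA example."""
    df = pd.DataFrame([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]], index=["f1"], columns=list("abcdef"))
    states = {s: ("A" if s in "abc" else "B") for s in "abcdef"}
    return ExpressionMatrix(df, states)


@pytest.fixture
def two_group_design():
    return StageDesign("AvB", ("a", "b", "c"), ("d", "e", "f"))


def random_matrix(n_features, group_sizes, seed, loc=8.0, scale=1.0):
    """A null matrix with labeled groups, no true signal."""
    rng = np.random.default_rng(seed)
    samples, states = [], {}
    for gi, size in enumerate(group_sizes):
        for r in range(size):
            sid = f"g{gi}_s{r}"
            samples.append(sid)
            states[sid] = f"G{gi}"
    vals = rng.normal(loc, scale, size=(n_features, len(samples)))
    df = pd.DataFrame(vals, index=[f"f{i:04d}" for i in range(n_features)], columns=samples)
    return ExpressionMatrix(df, states)


@pytest.fixture
def random_matrix_factory():
    return random_matrix
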