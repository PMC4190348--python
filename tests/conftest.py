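import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def small_counts():
    """A tiny two-condition count matrix with sample metadata."""
    from rxnet.expression import ExpressionMatrix

    values = pd.DataFrame(
        {
            "sib_1": [100, 5, 0, 40],
            "sib_2": [110, 6, 0, 38],
            "mut_1": [20, 4, 0, 41],
            "mut_2": [25, 3, 0, 39],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    meta = pd.DataFrame(
        {
            "condition": ["sibling", "sibling", "mutant", "mutant"],
            "replicate": ["1", "2", "1", "2"],
            "stage": ["13hpf"] * 4,
        },
        index=pd.Index(values.columns, name="sample"),
    )
    return ExpressionMatrix(values=values, units="counts", sample_meta=meta)


@pytest.fixture
def log_matrix():
    """A small stage-course matrix tagged log2rpkm."""
    from rxnet.expression import ExpressionMatrix

    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(5, 1, size=(6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(8)],
    )
    return ExpressionMatrix(values=values, units="log2rpkm")


@pytest.fixture(scope="session")
def default_pwm():
    from rxnet.motif import load_default_pwm

    return load_default_pwm()
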