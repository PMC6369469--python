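import logging

import numpy as np
import pandas as pd
import pytest

from lncnet.preprocess import ExpressionMatrix

logging.getLogger("lncnet").setLevel(logging.ERROR)


def make_matrix(values, scale="linear", probe_ids=None, n_case=None):
    """ExpressionMatrix from a 2-D array; first half of columns are case."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if n_case is None:
        n_case = n_samples // 2
    probe_ids = probe_ids or [f"P{i:03d}" for i in range(n_probes)]
    samples = [f"case_{i}" for i in range(n_case)] + [
        f"ctrl_{i}" for i in range(n_samples - n_case)
    ]
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=samples),
        groups=groups,
        scale=scale,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    return make_matrix([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]], n_case=1)
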