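import numpy as np
import pandas as pd
import pytest

from scshape.io import BASECOUNT_COLUMNS, BaseCountMatrix


def make_counts(records):
    """BaseCountMatrix from (cell, tx, pos, coverage, mutated, condition) tuples."""
    return BaseCountMatrix(pd.DataFrame(records, columns=BASECOUNT_COLUMNS))


def random_counts(rng, n_cells=5, length=30, mean_cov=50, rate=0.05, tx="tx1",
                  condition="treated"):
    rows = []
    for c in range(n_cells):
        cov = rng.poisson(mean_cov, size=length)
        mut = rng.binomial(cov, rate)
        for pos in range(length):
            if cov[pos] > 0:
                rows.append((f"c{c}", tx, pos, int(cov[pos]), int(mut[pos]), condition))
    return make_counts(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
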