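import numpy as np
import pandas as pd
import pytest

from steppekit.io_tables import GenotypeMatrix, MISSING


def make_matrix(calls, chroms=None, ids=None, ref=None, alt=None):
    """Build a GenotypeMatrix from a nested list / array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if chroms is None:
        chroms = ["1"] * m
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{k}" for k in range(m)],
            "chrom": [str(c) for c in chroms],
            "pos": np.arange(1, m + 1) * 100,
            "ref": ref if ref is not None else ["C"] * m,
            "alt": alt if alt is not None else ["G"] * m,
        }
    )
    if ids is None:
        ids = [f"I{k}" for k in range(n)]
    return GenotypeMatrix(individuals=ids, snps=snps, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n, m, missing_rate=0.2, x_fraction=0.0):
    calls = rng.integers(0, 2, size=(n, m)).astype(np.int8)
    calls[rng.random((n, m)) < missing_rate] = MISSING
    n_x = int(round(x_fraction * m))
    chroms = ["1"] * (m - n_x) + ["X"] * n_x
    return make_matrix(calls, chroms=chroms)
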