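import numpy as np
import pytest

from coevnet import Alignment


def aln_from_cols(*cols: str, ids=None, taxon=None) -> Alignment:
    """Build an alignment from column strings (each string = one column)."""
    n_rows = len(cols[0])
    rows = ["".join(c[r] for c in cols) for r in range(n_rows)]
    return Alignment(ids or [f"s{i}" for i in range(n_rows)], rows, taxon)


@pytest.fixture
def four_col_pair():
    """The canonical perfectly covarying 2-column toy: AACC / SSTT."""
    return aln_from_cols("AACC", "SSTT")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
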