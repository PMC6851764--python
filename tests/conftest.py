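import numpy as np
import pandas as pd
import pytest

from megxe.genodata import GenotypePanel


def make_panel(dosages, positions=None, chrom="1S", line_ids=None, **line_cols):
    """Small literal panel for unit tests."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if np.isscalar(chrom):
        chrom = [chrom] * m
    snp_map = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "id": [f"s{j}" for j in range(m)]}
    )
    if line_ids is None:
        line_ids = [f"L{i:03d}" for i in range(n)]
    lines = pd.DataFrame({"id": line_ids, **line_cols})
    return GenotypePanel(d, snp_map, lines)


@pytest.fixture
def tiny_panel():
    return make_panel(
        [[0, 2, 0, 2],
         [2, 0, 0, 2],
         [0, 0, 2, 0],
         [2, 2, 2, 0]]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
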