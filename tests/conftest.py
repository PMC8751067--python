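import numpy as np
import pandas as pd
import pytest

from snpanel.panel import GenotypePanel


def marker_frame(n, chrom="chr01", start=100, step=100):
    return pd.DataFrame(
        {
            "id": [f"m{i}" for i in range(n)],
            "chromosome": chrom,
            "position": [start + step * i for i in range(n)],
            "ref": "A",
            "alt": "T",
            "coding": False,
        }
    )


def make_panel(codes, chrom="chr01", positions=None):
    """Panel from a raw code matrix; markers named m0..m(k-1) on one chromosome."""
    codes = np.asarray(codes, dtype=np.int8)
    mdf = marker_frame(codes.shape[1], chrom=chrom)
    if positions is not None:
        mdf["position"] = positions
    ids = [f"v{i}" for i in range(codes.shape[0])]
    return GenotypePanel(ids, mdf, codes)


def random_panel(rng, n_varieties, n_markers, codes=(0, 2), distinct=True):
    """Random homozygous panel; resamples until varieties are pairwise distinct."""
    for _ in range(100):
        mat = rng.choice(codes, size=(n_varieties, n_markers)).astype(np.int8)
        if not distinct or np.unique(mat, axis=0).shape[0] == n_varieties:
            return make_panel(mat)
    raise AssertionError("could not draw a panel with distinct varieties")


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
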