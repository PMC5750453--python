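import numpy as np
import pytest

from postgwas.ld import HaplotypePanel
from postgwas.simulate import _flip_prob_for_corr


def make_panel(columns, pos=None, chrom=None, ids=None):
    """Build a small panel from a dict or list of 0/1 columns."""
    if isinstance(columns, dict):
        ids = list(columns)
        cols = [np.asarray(columns[s]) for s in ids]
    else:
        cols = [np.asarray(c) for c in columns]
        ids = ids or [f"snp{i}" for i in range(len(cols))]
    n = len(cols)
    return HaplotypePanel(
        snp_ids=ids,
        chrom=np.array(chrom if chrom is not None else ["1"] * n, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, n + 1) * 1000),
        alleles=[("A", "G")] * n,
        H=np.column_stack(cols),
    )


def correlated_column(founder, target_r2, rng):
    """Flip-copy of ``founder`` with pairwise r^2 approximately target_r2."""
    p = founder.mean()
    f = _flip_prob_for_corr(np.sqrt(target_r2), p)
    return founder ^ (rng.random(founder.size) < f).astype(np.uint8)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def fx():
    from postgwas.fixtures import fixtures

    return fixtures()
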