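import numpy as np
import pytest

from tempopg import FreqSeries, TemporalCounts


def make_counts(p, n=100, ploidy=2, generations=None, interval=1.0):
    """TemporalCounts whose frequencies are exactly p (p on the count grid)."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    L, K = p.shape
    counts = np.rint(p * ploidy * n).astype(int)
    return TemporalCounts(
        site_ids=[f"s{i}" for i in range(L)],
        generations=np.arange(K) if generations is None else np.asarray(generations),
        counts=counts,
        sample_sizes=np.full((L, K), n),
        ploidy=ploidy,
        interval=interval,
    )


def make_fs(p, n=100, ploidy=2, generations=None):
    """FreqSeries with arbitrary (not grid-aligned) frequencies p."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    tc = make_counts(np.clip(p, 0, 1), n=n, ploidy=ploidy, generations=generations)
    return FreqSeries(p_hat=p, parent=tc)


@pytest.fixture
def counts_factory():
    return make_counts


@pytest.fixture
def fs_factory():
    return make_fs


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
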