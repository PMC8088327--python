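import numpy as np
import pytest

from ivmix.ratio import RatioDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_dataset(theta, sigma, ids=None) -> RatioDataset:
    theta = np.asarray(theta, dtype=float)
    if np.isscalar(sigma):
        sigma = np.full(theta.size, float(sigma))
    ids = ids or [f"v{i}" for i in range(theta.size)]
    return RatioDataset(variant_ids=list(ids), theta_hat=theta, sigma_hat=np.asarray(sigma, float))


@pytest.fixture
def two_cluster_data():
    """Two tight, well-separated clouds at -1 and +1 (20 points each)."""
    r = np.random.default_rng(7)
    theta = np.r_[r.normal(-1.0, 0.05, 20), r.normal(1.0, 0.05, 20)]
    return make_dataset(theta, 0.05)
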