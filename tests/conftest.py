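import numpy as np
import pytest

from hopitx.data import HopitParams, SurveyDataset
from hopitx.simulation import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def toy_params():
    """Small, well-conditioned parameter set (K=3, J=2, p=2)."""
    return HopitParams(
        beta=np.array([0.8, -0.5]),
        gamma=np.array([[0.1, 0.3, -0.2], [0.2, 0.1, 0.1]]),
        theta=np.array([-0.5, 0.7]),
        sigma_u=0.4,
        sigma_v=0.8,
        alpha=0.05,
    )


@pytest.fixture(scope="session")
def toy_data():
    """Five-respondent dataset matching toy_params' shapes."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(5, 2))
    Z = np.hstack([np.ones((5, 1)), X])
    y = np.array([1, 2, 3, 2, 1])
    V = np.array([[1, 2], [2, 3], [3, 3], [1, 1], [2, 2]])
    return SurveyDataset(y=y, V=V, X=X, Z=Z, K=3)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset from the reference DGP (N=300, J=3)."""
    cfg = SimConfig(N=300, J=3, alpha=0.05, seed=42, n_reps=1)
    return simulate_dataset(cfg)
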