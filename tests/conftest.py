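import numpy as np
import pytest

from cvcausal import (
    BeatSeries,
    CouplingSpec,
    EmbeddingSpec,
    Universe,
    linear_detrend,
    normalize,
    simulate_coupled,
)


def make_universe(data: np.ndarray, labels=None) -> Universe:
    """Normalize columns of a data matrix into an analysis universe."""
    data = np.atleast_2d(data.T).T
    labels = labels or [f"y{i}" for i in range(data.shape[1])]
    return Universe(
        tuple(normalize(BeatSeries(data[:, i], label=l)) for i, l in enumerate(labels)),
        normalized=True,
    )


def ar1_universe(a: float, n: int, seed: int) -> Universe:
    """Single-series AR(1) universe with coefficient ``a``."""
    spec = CouplingSpec(n=n, self_coeffs=((a,),), couplings=(), noise_sd=(1.0,))
    data, _ = simulate_coupled(spec, seed=seed)
    return make_universe(data, ["y"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_universe(rng):
    """Trivariate white-noise universe of 64 beats."""
    return make_universe(rng.normal(size=(64, 3)), ["HP", "SAP", "RESP"])


@pytest.fixture
def univariate_spec():
    return EmbeddingSpec(0, (1,), 2)
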