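import numpy as np
import pytest

from expotraj import AnnualSeries, LCMMSpec, LinkFunction, TimeBasis


@pytest.fixture
def link():
    """Small monotone link on [0, 40] with mixed weights."""
    return LinkFunction((0.0, 10.0, 40.0), np.array([0.8, -0.5, 0.3]))


@pytest.fixture
def identity_link():
    """Weights making H(y) = y exactly on [0, 40]."""
    return LinkFunction.identity_like((0.0, 10.0, 40.0))


@pytest.fixture
def time_basis():
    return TimeBasis(inner_knots=(12.0, 24.0, 36.0), boundary_knots=(0.0, 45.0))


@pytest.fixture
def small_spec(time_basis):
    return LCMMSpec(n_classes=1, link_knots=(0.0, 10.0, 40.0), time_basis=time_basis)


@pytest.fixture
def tiny_series():
    """Five short annual series with within-subject structure."""
    rng = np.random.default_rng(42)
    out = []
    for i in range(5):
        n = int(rng.integers(3, 9))
        t = np.sort(rng.choice(np.arange(0, 45), size=n, replace=False)).astype(float)
        y = np.clip(rng.normal(12 + 0.1 * t, 4), 0.0, 40.0)
        out.append(AnnualSeries(f"S{i}", t, y))
    return out
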