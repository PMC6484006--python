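import numpy as np
import pytest

from somic import ClimateSpec, ForcingRecord, ModelParams, PoolState


@pytest.fixture(scope="session")
def released():
    return ModelParams.released()


@pytest.fixture
def constant_forcing():
    """Constant temperate forcing: 10 degC, moist, 3 t C/ha/y litter."""

    def make(n_months=12, temp=10.0, moisture=0.8, litter=0.25, clay=0.25, t0=0):
        return [
            ForcingRecord(time=t0 + t, temp=temp, moisture=moisture,
                          litter=litter, clay=clay)
            for t in range(n_months)
        ]

    return make


@pytest.fixture
def random_state():
    """Seeded generator of admissible random pool states."""
    rng = np.random.default_rng(42)

    def make():
        return PoolState(*rng.uniform(0.0, 50.0, 5))

    return make, rng


@pytest.fixture(scope="session")
def short_spec():
    """A 30-year synthetic climate, cheap enough for I/O round-trip tests."""
    return ClimateSpec(years=30, seed=7)
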