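import numpy as np
import pytest

import dietmix as dm


@pytest.fixture(scope="session")
def table1():
    return dm.builtin_scenario("table1")


@pytest.fixture(scope="session")
def hare():
    return dm.builtin_scenario("hare_a")


def make_plain_scenario(signals, consumer_mean, consumer_sd=0.2, offset=0.0,
                        constraints=(), groups=None):
    """Single-fraction, single-proxy scenario with fixed sources at uniform
    concentration — the classical non-routed linear mixing setup."""
    signals = np.asarray(signals, float)
    n = signals.size
    groups = tuple(groups) if groups else tuple(f"G{i}" for i in range(n))
    return dm.DietaryScenario(
        groups=groups,
        fractions=("F",),
        proxies=("P",),
        signal_mean=signals.reshape(n, 1, 1),
        signal_sd=np.zeros((n, 1, 1)),
        signal_ok=np.ones((n, 1, 1), bool),
        conc_mean=np.full((n, 1), 100.0),
        conc_sd=np.zeros((n, 1)),
        weight_mean=np.array([[100.0]]),
        weight_sd=np.zeros((1, 1)),
        offset_mean=np.array([float(offset)]),
        offset_sd=np.array([0.0]),
        consumer_mean=np.array([float(consumer_mean)]),
        consumer_sd=np.array([float(consumer_sd)]),
        constraints=tuple(constraints),
    )
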