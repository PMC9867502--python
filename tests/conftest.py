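import numpy as np
import pandas as pd
import pytest

from cpetml.cpetio import BreathTable, SecondTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_breath_table(rng, n_breaths=50, t_span=300.0):
    """A random but valid breath-domain record."""
    t = np.sort(rng.uniform(0, t_span, n_breaths))
    t += np.arange(n_breaths) * 1e-3  # enforce strict monotonicity
    df = pd.DataFrame({
        "t": t,
        "VO2": rng.uniform(300, 3000, n_breaths),
        "VCO2": rng.uniform(250, 3200, n_breaths),
        "VE": rng.uniform(8, 120, n_breaths),
        "Rf": rng.uniform(10, 55, n_breaths),
        "PetO2": rng.uniform(90, 120, n_breaths),
        "PetCO2": rng.uniform(28, 45, n_breaths),
        "HR": rng.uniform(60, 190, n_breaths),
    })
    return BreathTable(df)


@pytest.fixture
def breath_table(rng):
    return random_breath_table(rng)


@pytest.fixture
def tiny_breath_table():
    return BreathTable(pd.DataFrame({
        "t": [0.0, 10.0],
        "VO2": [300.0, 1300.0],
        "VCO2": [250.0, 1200.0],
        "VE": [10.0, 40.0],
        "Rf": [15.0, 30.0],
        "PetO2": [110.0, 100.0],
        "PetCO2": [32.0, 40.0],
    }))


def constant_second_table(n=120, **overrides):
    """A flat 1-Hz record, overridable per channel."""
    base = {"VO2": 1500.0, "VCO2": 1350.0, "VE": 40.0, "Rf": 30.0,
            "PetO2": 105.0, "PetCO2": 38.0, "HR": 120.0}
    base.update(overrides)
    df = pd.DataFrame({"t": np.arange(float(n))})
    for ch, v in base.items():
        df[ch] = np.full(n, v, dtype=float) if np.isscalar(v) else v
    return SecondTable(df)
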