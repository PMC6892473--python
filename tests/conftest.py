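from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import firesmoke as fs

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_scenario():
    """The default 20x20-cell, 8-unit, 2-year synthetic scenario (seed 0)."""
    return fs.generate_scenario(fs.ScenarioConfig(seed=0))


@pytest.fixture(scope="session")
def small_grid():
    return fs.build_grid(0.0, 0.0, 10.0, 4, 4)


@pytest.fixture()
def daily_series():
    """Factory: a daily pd.Series starting 2007-01-01 from a value list."""

    def make(values, start="2007-01-01"):
        idx = pd.date_range(start, periods=len(values), freq="D")
        return pd.Series(np.asarray(values, dtype=float), index=idx)

    return make


@pytest.fixture(scope="session")
def toy_dir():
    return DATA_DIR / "toy_scenario"
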