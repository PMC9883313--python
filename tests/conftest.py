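import numpy as np
import pandas as pd
import pytest

from probassoc import SimulationConfig, simulate_identifications


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated stream with planted units (shared across tests)."""
    cfg = SimulationConfig(seed=11, n_individuals=30, n_units=6,
                           n_days=8, events_per_day=4)
    df, diag = simulate_identifications(cfg, return_diagnostics=True)
    return df, diag


@pytest.fixture(scope="session")
def sim_default():
    """One default-sized stream (~5,000 identifications, b_true = 10)."""
    cfg = SimulationConfig(seed=0)
    return simulate_identifications(cfg)


def random_record_table(rng: np.random.Generator, n_records: int,
                        n_events: int = 4, n_individuals: int = 6,
                        ordinal_range: int = 40) -> pd.DataFrame:
    """Small random identification table for oracle-equivalence tests."""
    return pd.DataFrame({
        "individual": [f"i{k}" for k in rng.integers(n_individuals,
                                                     size=n_records)],
        "event": [f"e{k}" for k in rng.integers(n_events, size=n_records)],
        "ordinal": rng.integers(1, ordinal_range, size=n_records),
        "date": "2020-06-01",
    })
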