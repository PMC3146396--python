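import numpy as np
import pandas as pd
import pytest

import berksim as bk


@pytest.fixture(scope="session")
def base_series() -> bk.PollutantSeries:
    """CO-like base-case series over the full 2,192-day study period."""
    cfg = bk.WorldConfig(n_days=2192, n_sites=1, seed=11)
    return bk.generate_monitor_field(cfg).series["S00"]


@pytest.fixture(scope="session")
def confounders() -> pd.DataFrame:
    return bk.generate_confounders(2192, seed=12)


@pytest.fixture(scope="session")
def counts_plain(base_series) -> pd.Series:
    """Counts generated from the base series alone (no confounder effects)."""
    hc = bk.HealthConfig(seed=13)
    return bk.generate_health_counts(base_series, None, hc)


@pytest.fixture(scope="session")
def fit_true_plain(base_series, counts_plain) -> bk.EpiFit:
    return bk.fit_quasipoisson(counts_plain, base_series)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
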