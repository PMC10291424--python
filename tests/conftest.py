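import numpy as np
import pandas as pd
import pytest

from copial import Period, PeriodTable, SyntheticConfig, default_period_grid


@pytest.fixture(scope="session")
def grid14() -> PeriodTable:
    return default_period_grid()


@pytest.fixture()
def two_period_grid() -> PeriodTable:
    return PeriodTable((Period("early", 600, 679), Period("late", 680, 759)))


@pytest.fixture()
def small_config(grid14) -> SyntheticConfig:
    """A fast, fully defaulted synthetic world on the 14-period grid."""
    return SyntheticConfig(n_cells=20, n_settlements=25, houses_per_period=60, seed=7)


@pytest.fixture()
def toy_climate() -> pd.DataFrame:
    """10 cells x 1 year; cells 0-3 in niche, 4-9 out (precip too low)."""
    return pd.DataFrame(
        {
            "cell_id": np.arange(10),
            "year": 700,
            "precip_cm": [40.0] * 4 + [20.0] * 6,
            "fgdd": [2000.0] * 10,
        }
    )


def brute_force_gini(values, corrected=False):
    """O(n^2) pairwise oracle: G = sum|xi-xj| / (2 n^2 mu)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    g = np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())
    return g * n / (n - 1) if corrected else g
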