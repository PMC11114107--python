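import numpy as np
import pandas as pd
import pytest

from symbioclim.synthetic import SimConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_study():
    """3 locations x 12 hosts, short climate: fast end-to-end material."""
    cfg = SimConfig(n_locations=3, hosts_per_location=12, years=10, seed=101)
    hosts, locations, precip, truth = simulate_study(cfg)
    return cfg, hosts, locations, precip, truth


@pytest.fixture(scope="session")
def recovery_study():
    """Informative recovery design: wide predictability contrast between
    locations (per-location seasonal amplitudes U(0, 4), low climate noise)."""
    cfg = SimConfig(
        n_locations=30, hosts_per_location=50, years=60,
        amplitude_range=(0.0, 4.0), noise_sd=0.3,
        beta0=-1.0, beta_pred=1.0, tau=0.5, seed=42,
    )
    hosts, locations, precip, truth = simulate_study(cfg)
    return cfg, hosts, locations, precip, truth


def monthly_frame(values_by_year_month):
    """Helper: long-format precip frame from {(year, month): mm}."""
    rows = [
        {"year": y, "month": m, "precip_mm": v}
        for (y, m), v in values_by_year_month.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture()
def seasonal_series():
    """10 years, Jan-Jun dry (10 mm), Jul-Dec wet (1000 mm): perfectly
    contingent two-state climate."""
    years = np.repeat(np.arange(1901, 1911), 12)
    months = np.tile(np.arange(1, 13), 10)
    precip = np.where(months <= 6, 10.0, 1000.0)
    return pd.DataFrame({"year": years, "month": months, "precip_mm": precip})


@pytest.fixture()
def constant_series():
    years = np.repeat(np.arange(1901, 1911), 12)
    months = np.tile(np.arange(1, 13), 10)
    return pd.DataFrame({"year": years, "month": months, "precip_mm": 50.0})
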