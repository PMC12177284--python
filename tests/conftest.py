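"""Shared fixtures: reference simulations are expensive, so run each once."""

import numpy as np
import pandas as pd
import pytest

from rhizoflux import reference_scenarios, simulate, sample_sensors, segment_diel, daily_uptake_rate


@pytest.fixture(scope="session")
def scenarios():
    return reference_scenarios(seed=0)


@pytest.fixture(scope="session")
def noflow_result(scenarios):
    return simulate(scenarios["no-flow"])


@pytest.fixture(scope="session")
def baseline_result(scenarios):
    return simulate(scenarios["baseline-drying"])


@pytest.fixture(scope="session")
def two_rains_result(scenarios):
    return simulate(scenarios["two-rains"])


@pytest.fixture(scope="session")
def depth_invariant_result(scenarios):
    return simulate(scenarios["depth-invariant-psi0"])


@pytest.fixture(scope="session")
def baseline_series(baseline_result):
    """Noisy virtual-sensor series for the baseline dry-down."""
    return sample_sensors(baseline_result)


def uptake_frame(series, dates, **segment_kw):
    """Daily uptake rows for a span of dates (helper shared by tests)."""
    rows = []
    for day in dates:
        windows = segment_diel(series, day, **segment_kw)
        for depth, w in sorted(windows.items()):
            u = daily_uptake_rate(w)
            rows.append(
                {"date": pd.Timestamp(day), "depth": depth, "s": u.s_prime, "valid": u.valid}
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def baseline_uptake(baseline_series):
    dates = pd.date_range("2022-04-02", "2022-04-29")
    return uptake_frame(baseline_series, dates)
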