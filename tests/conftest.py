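import numpy as np
import pandas as pd
import pytest

import lagcrossover as lc
from lagcrossover.exposure import ExposureFields, Grid, LocalitySeries


@pytest.fixture(scope="session")
def small_study():
    """One simulated study with a nonzero lag06 truth of 2% per 10 ug/m3."""
    scenario = lc.SyntheticScenario(
        true_lag_betas_pm=lc.betas_for_lag06_percent(2.0),
        baseline_rate=0.3,
        seed=11,
        date_range=("2004-01-01", "2005-12-31"),
    )
    return lc.simulate_study(scenario)


@pytest.fixture(scope="session")
def small_analysis(small_study):
    analysis, exclusions = lc.filter_records(
        small_study.records, "2004-02-01", "2005-12-31"
    )
    return analysis, exclusions


@pytest.fixture(scope="session")
def small_rows(small_study, small_analysis):
    analysis, _ = small_analysis
    rows, drops = lc.build_strata_table(analysis, small_study.series)
    return rows, drops


def constant_series(value_pm=20.0, value_temp=15.0, n_days=120, locality_ids=("L1",)):
    """A locality series with constant exposures, complete everywhere."""
    dates = pd.date_range("2004-01-01", periods=n_days, freq="D")
    n = len(locality_ids)
    return LocalitySeries(
        dates=dates,
        locality_ids=list(locality_ids),
        pm=np.full((n_days, n), float(value_pm)),
        temp=np.full((n_days, n), float(value_temp)),
        complete=np.ones((n_days, n), dtype=bool),
    )


@pytest.fixture
def const_series():
    return constant_series()
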