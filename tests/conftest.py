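import numpy as np
import pytest

from survtrend import IndividualRecord, TrueTrend, make_life_table


@pytest.fixture(scope="session")
def zero_life_table():
    return make_life_table("x", "m", range(1960, 2040), (0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def const_life_table():
    # constant hazard 0.01/year at every age and year
    return make_life_table("x", "m", range(1960, 2040), (0.01, 0.0, 1.0))


@pytest.fixture(scope="session")
def makeham_life_table():
    return make_life_table("x", "m", range(1960, 2040), (5e-4, 2e-5, 0.09))


def random_cohort(rng, n, *, mean_fu=4.0, with_entry=False, year_span=(1995.0, 2015.0)):
    """Small random cohort (records, entry) for oracle comparisons."""
    records, entries = [], []
    for i in range(n):
        t = rng.exponential(mean_fu)
        cens = rng.uniform(0.5, 8.0)
        fu = max(min(t, cens), 1e-3)
        records.append(
            IndividualRecord(
                id=str(i),
                country="x",
                sex="m",
                age_at_dx=float(rng.uniform(20, 88)),
                dx_year=float(rng.uniform(*year_span)),
                follow_up=float(fu),
                status="died" if t < cens else "censored",
            )
        )
        entries.append(float(rng.uniform(0.0, fu * 0.5)) if with_entry else 0.0)
    return records, entries


@pytest.fixture(scope="session")
def fitted_pair():
    """A (five_year, one_year) fitted pair shared across feature tests."""
    from survtrend import TrendModelSpec, fit_trend, simulate_survival_points

    t5 = {
        "a_m": TrueTrend.logistic("a_m", "5y", 0.35, 0.70, 1995.0, 0.12),
        "b_f": TrueTrend.linear("b_f", "5y", 1971, 0.40, 0.005),
    }
    t1 = {
        "a_m": TrueTrend.logistic("a_m", "1y", 0.60, 0.90, 1995.0, 0.12),
        "b_f": TrueTrend.linear("b_f", "1y", 1971, 0.65, 0.004),
    }
    p5 = simulate_survival_points(t5, se_level=0.5, seed=11)
    p1 = simulate_survival_points(t1, se_level=0.5, seed=12)
    five = fit_trend(p5, TrendModelSpec(draws=1500, seed=21), metric="5y")
    one = fit_trend(p1, TrendModelSpec(draws=1500, seed=22), metric="1y")
    return five, one


def seeded_rng(seed):
    return np.random.default_rng(seed)
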