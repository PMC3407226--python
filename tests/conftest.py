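from datetime import date

import numpy as np
import pandas as pd
import pytest

from adstar.calendar_ads import AdsCalendar, AdsEvent, assign_lags
from adstar.panel import build_panel
from adstar.simulate import ScenarioConfig, generate, scaled_down_config


@pytest.fixture(scope="session")
def toy_calendar() -> AdsCalendar:
    """30-day window with two closely spaced events (ends day 10 and day 14)."""
    return AdsCalendar(
        events=(
            AdsEvent(date(2001, 1, 9), date(2001, 1, 10)),
            AdsEvent(date(2001, 1, 13), date(2001, 1, 14)),
        ),
        study_start=date(2001, 1, 1),
        study_end=date(2001, 1, 30),
    )


@pytest.fixture(scope="session")
def small_scenario():
    """3 districts x 2 years, reported-effect preset, fixed seed."""
    panels, truth = generate(scaled_down_config(seed=11))
    return panels["all"], truth


@pytest.fixture(scope="session")
def tiny_scenario():
    """3 districts x 60 days: small enough for dense oracles."""
    cfg = ScenarioConfig(
        n_districts=3,
        study_start=date(2001, 3, 1),
        study_end=date(2001, 4, 29),
        calendar="random",
        n_events=3,
        effects="all",
        age_groups=("all",),
        phi=1.5,
        seed=5,
    )
    panels, truth = generate(cfg)
    return panels["all"], truth


def manual_panel(n_days=14, districts=("A", "B"), counts_value=None, seed=0):
    """Hand-assembled panel over a short window with a one-event calendar."""
    start, end = date(2001, 1, 1), date(2001, 1, 1) + pd.Timedelta(
        days=n_days - 1
    ).to_pytimedelta()
    cal = AdsCalendar(
        events=(AdsEvent(date(2001, 1, 3), date(2001, 1, 4)),),
        study_start=start,
        study_end=end,
    )
    lag = assign_lags(cal)
    rng = np.random.default_rng(seed)
    idx = pd.date_range(start, end, freq="D")
    rows = []
    for d in districts:
        for ts in idx:
            c = counts_value if counts_value is not None else rng.poisson(50)
            rows.append({"date": ts, "district": d, "visits": c})
    counts = pd.DataFrame(rows)
    temps = pd.Series(20.0 + rng.normal(size=len(idx)), index=idx)
    pops = {d: 1000 * (i + 1) for i, d in enumerate(districts)}
    edges = [(districts[i], districts[i + 1]) for i in range(len(districts) - 1)]
    return build_panel(counts, temps, pops, edges, lag), cal
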