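import datetime as dt

import numpy as np
import pandas as pd
import pytest

from fusiondesign import CarcassSearch, FlightCount


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


def make_search(day, site="impact", period="before", n_carcass=1.0,
                interval_days=2, year=2020):
    date = dt.date(year, 1, 1) + dt.timedelta(days=day)
    return CarcassSearch(search_id=f"{site}-{day}", date=date, site=site,
                         period=period, n_carcass=n_carcass,
                         interval_days=interval_days)


def make_flight(day, site="impact", period="before", individuals=100,
                hours=4.0, species_group="geese", point="P1", year=2020):
    date = dt.date(year, 1, 1) + dt.timedelta(days=day)
    return FlightCount(date=date, counting_point=point, site=site,
                       period=period, species_group=species_group,
                       individuals=individuals, hours=hours)


@pytest.fixture
def survey_tables(tmp_path, rng):
    """Small but fittable carcass + flight CSVs for both sites and periods."""
    from fusiondesign import write_carcass_table, write_flight_table

    searches, flights = [], []
    day = 0
    for period, lam in (("before", 2.0), ("after", 1.2)):
        for k in range(10):
            day += 3
            for site in ("impact", "control"):
                searches.append(make_search(
                    day, site=site, period=period,
                    n_carcass=float(rng.poisson(lam)) * 1.3, interval_days=3))
            flights.append(make_flight(day - 1, site="impact", period=period,
                                       individuals=int(rng.poisson(300)), hours=4.0))
            flights.append(make_flight(day - 1, site="control", period=period,
                                       individuals=int(rng.poisson(250)), hours=4.0))
            flights.append(make_flight(day - 1, site="impact", period=period,
                                       individuals=int(rng.poisson(40)), hours=4.0,
                                       species_group="gulls"))
        day += 30
    carcass_path = tmp_path / "carcass.csv"
    flight_path = tmp_path / "flights.csv"
    write_carcass_table(searches, carcass_path)
    write_flight_table(flights, flight_path)
    return carcass_path, flight_path, searches, flights
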