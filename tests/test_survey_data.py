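"""Survey-table parsing, validation and the flight-pooling rule."""

import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fusiondesign import (
    CarcassSearch,
    ConfigError,
    FlightCount,
    FusionObservation,
    ValidationError,
    compute_exposure,
    pool_flights,
    read_carcass_table,
    read_flight_table,
    write_carcass_table,
    write_flight_table,
)
from conftest import make_flight, make_search


class TestCarcassTable:
    def test_identity_parse(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "date,site,period,n_carcass,interval_days\n"
            "2020-03-01,impact,before,1.9,2\n"
            "2020-03-01,control,before,0.0,2\n"
            "2021-03-01,Impact,After,3.8,5\n"
            "2021-03-01,CONTROL,after,1.0,5\n")
        records = read_carcass_table(path)
        assert len(records) == 4
        assert {(r.site, r.period) for r in records} == {
            ("impact", "before"), ("control", "before"),
            ("impact", "after"), ("control", "after")}
        assert records[0].n_carcass == 1.9 and records[0].interval_days == 2

    def test_negative_count_names_row(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("date,site,period,n_carcass,interval_days\n"
                        "2020-03-01,impact,before,1.0,2\n"
                        "2020-03-03,impact,before,-1.0,2\n")
        with pytest.raises(ValidationError, match="row 1"):
            read_carcass_table(path)

    def test_missing_column_is_config_error(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("date,site,period,count,interval_days\n"
                        "2020-03-01,impact,before,1.0,2\n")
        with pytest.raises(ConfigError, match="n_carcass"):
            read_carcass_table(path)
        # a column map fixes it
        records = read_carcass_table(path, column_map={"n_carcass": "count"})
        assert records[0].n_carcass == 1.0

    def test_duplicate_site_date_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("date,site,period,n_carcass,interval_days\n"
                        "2020-03-01,impact,before,1.0,2\n"
                        "2020-03-01,impact,before,2.0,2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_carcass_table(path)

    def test_round_trip(self, tmp_path):
        records = [make_search(d, site=s, period=p, n_carcass=1.3 * d + 0.1,
                               interval_days=2)
                   for d in (2, 4, 6) for s in ("impact", "control")
                   for p in (("before",) if d < 6 else ("after",))]
        path = tmp_path / "out.csv"
        write_carcass_table(records, path)
        back = read_carcass_table(path)
        assert len(back) == len(records)
        for a, b in zip(sorted(records, key=lambda r: (r.site, r.date)),
                        sorted(back, key=lambda r: (r.site, r.date))):
            assert (a.date, a.site, a.period) == (b.date, b.site, b.period)
            assert a.n_carcass == pytest.approx(b.n_carcass)
            assert a.interval_days == b.interval_days


class TestFlightTable:
    def _write(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text(
            "date,site,period,counting_point,species_group,individuals,hours\n"
            "2020-03-01,impact,before,P1,geese,120,4\n"
            "2020-03-01,impact,before,P1,gulls,30,4\n"
            "2020-03-08,control,before,P2,geese,80,4\n")
        return path

    def test_species_filter(self, tmp_path):
        records = read_flight_table(self._write(tmp_path), species_group="geese")
        assert len(records) == 2
        assert all(r.species_group == "geese" for r in records)

    def test_same_date_point_different_groups(self, tmp_path):
        records = read_flight_table(self._write(tmp_path), species_group="gulls")
        assert len(records) == 1 and records[0].individuals == 30

    def test_unknown_group_warns_and_is_empty(self, tmp_path):
        with pytest.warns(UserWarning, match="not present"):
            records = read_flight_table(self._write(tmp_path), species_group="swans")
        assert records == []

    def test_zero_hours_rejected(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text(
            "date,site,period,counting_point,species_group,individuals,hours\n"
            "2020-03-01,impact,before,P1,geese,120,0\n")
        with pytest.raises(ValidationError, match="hours"):
            read_flight_table(path)


class TestPooling:
    def test_each_interval_with_data(self):
        searches = [make_search(0, n_carcass=0.0), make_search(2, n_carcass=1.0),
                    make_search(4, n_carcass=2.0)]
        flights = [make_flight(1, individuals=100, hours=4.0),
                   make_flight(3, individuals=50, hours=2.0)]
        obs = pool_flights(flights, searches, site="impact")
        assert [(o.pooled_individuals, o.pooled_hours) for o in obs] == [(100, 4.0), (50, 2.0)]
        assert [o.n_carcass for o in obs] == [1.0, 2.0]
        assert [o.interval_days for o in obs] == [2, 2]

    def test_empty_interval_rolls_forward(self):
        searches = [make_search(0, n_carcass=0.0), make_search(2, n_carcass=1.0),
                    make_search(4, n_carcass=2.0)]
        flights = [make_flight(3, individuals=50, hours=2.0)]
        obs = pool_flights(flights, searches, site="impact")
        assert len(obs) == 1
        assert obs[0].n_carcass == 3.0
        assert obs[0].interval_days == 4
        assert (obs[0].pooled_individuals, obs[0].pooled_hours) == (50, 2.0)

    def test_full_coverage_count(self):
        searches = [make_search(2 * k, n_carcass=float(k)) for k in range(20)]
        flights = [make_flight(2 * k - 1, individuals=10 + k, hours=2.0)
                   for k in range(1, 20)]
        obs = pool_flights(flights, searches, site="impact")
        assert len(obs) == len(searches) - 1

    def test_no_flight_data_errors(self):
        searches = [make_search(0), make_search(2)]
        with pytest.raises(ValidationError, match="impossible|no flight"):
            pool_flights([make_flight(1, site="control")], searches, site="impact")

    def test_conservation_and_order_invariance(self, rng):
        searches = [make_search(3 * k, n_carcass=float(rng.poisson(2)),
                                interval_days=3) for k in range(12)]
        flights = [make_flight(d, individuals=int(rng.poisson(60)),
                               hours=float(rng.uniform(1, 5)), point=f"P{d%2}")
                   for d in range(1, 34)]
        obs = pool_flights(flights, searches)
        covered = [f for f in flights if searches[0].date < f.date <= searches[-1].date]
        assert sum(o.pooled_individuals for o in obs) == sum(f.individuals for f in covered)
        assert sum(o.pooled_hours for o in obs) == pytest.approx(
            sum(f.hours for f in covered))
        assert sum(o.n_carcass for o in obs) == pytest.approx(
            sum(s.n_carcass for s in searches[1:]))
        shuffled = list(flights)
        rng.shuffle(shuffled)
        assert pool_flights(shuffled, searches[::-1]) == obs

    def test_session_on_search_date_closes_interval(self):
        # half-open (prev, current]: a session exactly on the search date
        # belongs to the interval that search closes
        searches = [make_search(0), make_search(2, n_carcass=1.0),
                    make_search(4, n_carcass=2.0)]
        flights = [make_flight(2, individuals=70, hours=2.0),
                   make_flight(3, individuals=10, hours=1.0)]
        obs = pool_flights(flights, searches)
        assert obs[0].pooled_individuals == 70
        assert obs[1].pooled_individuals == 10


class TestExposure:
    @pytest.mark.parametrize("days,individuals,hours,expected", [
        (2, 1254, 4.0, 627.0),
        (1, 0, 3.0, 0.0),
        (5, 100, 8.0, 62.5),
    ])
    def test_arithmetic(self, days, individuals, hours, expected):
        obs = FusionObservation(date=dt.date(2020, 3, 1), jday=61, period="before",
                                n_carcass=1.0, interval_days=days,
                                pooled_individuals=individuals, pooled_hours=hours)
        assert compute_exposure(obs) == pytest.approx(expected)
        assert obs.exposure_A == pytest.approx(expected)

    def test_zero_hours_with_individuals_errors(self):
        with pytest.raises(ValidationError):
            FusionObservation(date=dt.date(2020, 3, 1), jday=61, period="before",
                              n_carcass=1.0, interval_days=2,
                              pooled_individuals=10, pooled_hours=0.0)

    @given(days=st.integers(1, 50), individuals=st.integers(1, 10_000),
           hours=st.floats(0.5, 100, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_homogeneity(self, days, individuals, hours):
        base = FusionObservation(date=dt.date(2020, 3, 1), jday=61, period="before",
                                 n_carcass=0.0, interval_days=days,
                                 pooled_individuals=individuals, pooled_hours=hours)
        scaled = FusionObservation(date=dt.date(2020, 3, 1), jday=61, period="before",
                                   n_carcass=0.0, interval_days=days,
                                   pooled_individuals=2 * individuals,
                                   pooled_hours=2 * hours)
        doubled_days = FusionObservation(date=dt.date(2020, 3, 1), jday=61,
                                         period="before", n_carcass=0.0,
                                         interval_days=2 * days,
                                         pooled_individuals=individuals,
                                         pooled_hours=hours)
        assert scaled.exposure_A == pytest.approx(base.exposure_A, rel=1e-12)
        assert doubled_days.exposure_A == pytest.approx(2 * base.exposure_A, rel=1e-12)
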