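"""Survey tables and flight pooling for fusion-design diverter studies.

This module holds the data model for the two field tables a wire-marking
effectiveness study produces — corrected carcass counts per search and bird
flight-observation sessions — together with delimited-text I/O and the
pooling rule that merges flight sessions into the search intervals of the
carcass record, producing exposure-ready fusion observations.

The exposure measure is ``A = interval_days * individuals / hours``: the
flight intensity observed between two consecutive carcass searches, scaled
by the length of the search interval. Downstream models use ``log(1 + A)``
as an offset, so a carcass count becomes a collision *rate* per observed
crossing.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ConfigError",
    "ValidationError",
    "CarcassSearch",
    "FlightCount",
    "FusionObservation",
    "read_carcass_table",
    "read_flight_table",
    "write_carcass_table",
    "write_flight_table",
    "pool_flights",
    "compute_exposure",
    "searches_to_frame",
    "flights_to_frame",
    "observations_to_frame",
]

SITES = ("impact", "control")
PERIODS = ("before", "after")

CARCASS_COLUMNS = ("date", "site", "period", "n_carcass", "interval_days")
FLIGHT_COLUMNS = ("date", "site", "period", "counting_point", "species_group",
                  "individuals", "hours")


class ConfigError(ValueError):
    """A column mapping or configuration key does not match the input."""


class ValidationError(ValueError):
    """An input row or record violates a domain invariant."""


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value).strip())


def _norm_level(value, allowed: Sequence[str], what: str):
    v = str(value).strip().lower()
    if v not in allowed:
        raise ValidationError(f"{what} must be one of {allowed}, got {value!r}")
    return v


@dataclass(frozen=True)
class CarcassSearch:
    """One carcass search at one site on one date.

    ``n_carcass`` is the *corrected* carcass count (scaled for persistence,
    detectability and off-transect mortality upstream of this package) and
    is therefore allowed to be non-integer. ``interval_days`` is the number
    of days since the previous search at the same site.
    """

    search_id: str
    date: dt.date
    site: str
    period: str
    n_carcass: float
    interval_days: int

    def __post_init__(self):
        object.__setattr__(self, "date", _parse_date(self.date))
        object.__setattr__(self, "site", _norm_level(self.site, SITES, "site"))
        object.__setattr__(self, "period", _norm_level(self.period, PERIODS, "period"))
        if not self.n_carcass >= 0:
            raise ValidationError(f"n_carcass must be >= 0, got {self.n_carcass}")
        if int(self.interval_days) != self.interval_days or self.interval_days < 1:
            raise ValidationError(f"interval_days must be a positive integer, got {self.interval_days}")
        object.__setattr__(self, "n_carcass", float(self.n_carcass))
        object.__setattr__(self, "interval_days", int(self.interval_days))


@dataclass(frozen=True)
class FlightCount:
    """One flight-observation session at one counting point."""

    date: dt.date
    counting_point: str
    site: str
    period: str
    species_group: str
    individuals: int
    hours: float

    def __post_init__(self):
        object.__setattr__(self, "date", _parse_date(self.date))
        object.__setattr__(self, "site", _norm_level(self.site, SITES, "site"))
        object.__setattr__(self, "period", _norm_level(self.period, PERIODS, "period"))
        if int(self.individuals) != self.individuals or self.individuals < 0:
            raise ValidationError(f"individuals must be a non-negative integer, got {self.individuals}")
        if not self.hours > 0:
            raise ValidationError(f"hours must be > 0, got {self.hours}")
        object.__setattr__(self, "individuals", int(self.individuals))
        object.__setattr__(self, "hours", float(self.hours))


@dataclass(frozen=True)
class FusionObservation:
    """A carcass count paired with the flight exposure of its search interval."""

    date: dt.date
    jday: int
    period: str
    n_carcass: float
    interval_days: int
    pooled_individuals: int
    pooled_hours: float
    exposure_A: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "date", _parse_date(self.date))
        object.__setattr__(self, "period", _norm_level(self.period, PERIODS, "period"))
        if self.exposure_A is None:
            object.__setattr__(
                self,
                "exposure_A",
                _exposure(self.interval_days, self.pooled_individuals, self.pooled_hours),
            )
        if not 1 <= self.jday <= 366:
            raise ValidationError(f"jday must lie in [1, 366], got {self.jday}")
        if not self.n_carcass >= 0:
            raise ValidationError(f"n_carcass must be >= 0, got {self.n_carcass}")


def _exposure(interval_days: float, individuals: float, hours: float) -> float:
    if individuals == 0:
        return 0.0
    if hours <= 0:
        raise ValidationError(
            f"pooled_hours must be positive when pooled_individuals > 0 "
            f"(got individuals={individuals}, hours={hours})"
        )
    return float(interval_days) * float(individuals) / float(hours)


def compute_exposure(obs: FusionObservation) -> float:
    """Exposure A = interval_days x pooled_individuals / pooled_hours.

    Zero individuals give A = 0 regardless of hours; positive individuals
    with zero observation hours are an error (the rate is undefined).
    """
    return _exposure(obs.interval_days, obs.pooled_individuals, obs.pooled_hours)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _apply_column_map(frame: pd.DataFrame, column_map: Mapping[str, str] | None,
                      required: Sequence[str]) -> pd.DataFrame:
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    frame = frame.rename(columns=rename)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ConfigError(
            f"missing column(s) {missing}; present: {list(frame.columns)}; "
            f"adjust the column map"
        )
    return frame


def read_carcass_table(path, column_map: Mapping[str, str] | None = None,
                       delimiter: str = ",") -> list[CarcassSearch]:
    """Read a carcass-search table from delimited text.

    ``column_map`` maps canonical field names (``date``, ``site``,
    ``period``, ``n_carcass``, ``interval_days``, optionally ``search_id``)
    to the column names used in the file. Rows violating an invariant raise
    a :class:`ValidationError` naming the offending row.
    """
    frame = pd.read_csv(path, sep=delimiter)
    frame = _apply_column_map(frame, column_map, CARCASS_COLUMNS)
    records = []
    seen = set()
    for idx, row in frame.iterrows():
        try:
            rec = CarcassSearch(
                search_id=str(row.get("search_id", idx)),
                date=row["date"], site=row["site"], period=row["period"],
                n_carcass=row["n_carcass"], interval_days=row["interval_days"],
            )
        except ValidationError as err:
            raise ValidationError(f"row {idx}: {err}") from err
        key = (rec.site, rec.date)
        if key in seen:
            raise ValidationError(f"row {idx}: duplicate (site, date) = {key}")
        seen.add(key)
        records.append(rec)
    return records


def read_flight_table(path, column_map: Mapping[str, str] | None = None,
                      species_group: str | None = None, delimiter: str = ",",
                      ) -> list[FlightCount]:
    """Read a flight-count table, optionally restricted to one species group.

    An unknown ``species_group`` yields an empty list plus a warning rather
    than an error, so per-group batch analyses degrade gracefully.
    """
    frame = pd.read_csv(path, sep=delimiter)
    frame = _apply_column_map(frame, column_map, FLIGHT_COLUMNS)
    if species_group is not None:
        groups = set(frame["species_group"].astype(str))
        if species_group not in groups:
            warnings.warn(
                f"species group {species_group!r} not present (groups: {sorted(groups)}); "
                f"returning no records", stacklevel=2)
        frame = frame[frame["species_group"].astype(str) == species_group]
    records = []
    for idx, row in frame.iterrows():
        try:
            records.append(FlightCount(
                date=row["date"], counting_point=str(row["counting_point"]),
                site=row["site"], period=row["period"],
                species_group=str(row["species_group"]),
                individuals=row["individuals"], hours=row["hours"],
            ))
        except ValidationError as err:
            raise ValidationError(f"row {idx}: {err}") from err
    return records


def searches_to_frame(searches: Iterable[CarcassSearch]) -> pd.DataFrame:
    rows = [{"date": s.date.isoformat(), "site": s.site, "period": s.period,
             "n_carcass": s.n_carcass, "interval_days": s.interval_days,
             "search_id": s.search_id} for s in searches]
    return pd.DataFrame(rows)


def flights_to_frame(flights: Iterable[FlightCount]) -> pd.DataFrame:
    rows = [{"date": f.date.isoformat(), "site": f.site, "period": f.period,
             "counting_point": f.counting_point, "species_group": f.species_group,
             "individuals": f.individuals, "hours": f.hours} for f in flights]
    return pd.DataFrame(rows)


def observations_to_frame(observations: Iterable[FusionObservation]) -> pd.DataFrame:
    rows = [{"date": o.date.isoformat(), "jday": o.jday, "period": o.period,
             "n_carcass": o.n_carcass, "interval_days": o.interval_days,
             "pooled_individuals": o.pooled_individuals,
             "pooled_hours": o.pooled_hours, "exposure_A": o.exposure_A}
            for o in observations]
    return pd.DataFrame(rows)


def write_carcass_table(searches: Iterable[CarcassSearch], path, delimiter: str = ",") -> None:
    searches_to_frame(searches)[list(CARCASS_COLUMNS) + ["search_id"]].to_csv(
        path, sep=delimiter, index=False)


def write_flight_table(flights: Iterable[FlightCount], path, delimiter: str = ",") -> None:
    flights_to_frame(flights)[list(FLIGHT_COLUMNS)].to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# flight pooling
# ---------------------------------------------------------------------------

def pool_flights(flights: Sequence[FlightCount], searches: Sequence[CarcassSearch],
                 site: str = "impact") -> list[FusionObservation]:
    """Pool flight sessions into carcass-search intervals at one site.

    Each search after the first closes the half-open interval
    ``(previous search date, search date]``; all flight sessions in that
    window are summed and attributed to the search's carcass count. A
    search whose window contains no flight session does not form its own
    observation: its carcasses and interval days accumulate forward until a
    window with flight data closes the observation. A trailing run of
    searches that is never closed by flight data is dropped.

    The leading search carries carcasses from before monitoring started and
    never forms an observation.
    """
    site = _norm_level(site, SITES, "site")
    searches = sorted((s for s in searches if s.site == site), key=lambda s: s.date)
    sessions = sorted((f for f in flights if f.site == site), key=lambda f: f.date)
    if not sessions:
        raise ValidationError(f"no flight data for site {site!r}; fusion analysis impossible")
    if len(searches) < 2:
        raise ValidationError(f"need at least two searches at site {site!r} to form an interval")

    out: list[FusionObservation] = []
    acc_carcass = 0.0
    acc_days = 0
    window_start = searches[0].date
    for search in searches[1:]:
        acc_carcass += search.n_carcass
        acc_days += search.interval_days
        in_window = [f for f in sessions if window_start < f.date <= search.date]
        if not in_window:
            continue  # roll forward into the next interval
        out.append(FusionObservation(
            date=search.date,
            jday=search.date.timetuple().tm_yday,
            period=search.period,
            n_carcass=acc_carcass,
            interval_days=acc_days,
            pooled_individuals=sum(f.individuals for f in in_window),
            pooled_hours=sum(f.hours for f in in_window),
        ))
        acc_carcass = 0.0
        acc_days = 0
        window_start = search.date
    if not out:
        raise ValidationError(
            f"no search interval at site {site!r} contains flight data; fusion analysis impossible")
    return out
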