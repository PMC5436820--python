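"""CSV schemas, closure calendar, price schedule and config file handling.

All files are plain text.  Data CSVs may carry ``#``-prefixed provenance
header lines (version, seed, config hash) which readers skip.  Dates are
ISO-8601; months are addressed as ``YYYY-MM``.

Schemas
-------
daily_surveys.csv : date, site, boats_at_sea, boats_inactive
boat_records.csv  : date, site, activity, n_fishers, n_pots, n_lobsters,
                    total_weight_kg
lobsters.csv      : date, species, tl_mm, cl_mm, sex, berried
ntz_calendar.csv  : open_start, open_end          (inclusive intervals)
price_schedule.csv: effective_from, price_mga_per_kg
"""

from __future__ import annotations

import datetime as dt
import io
from dataclasses import dataclass

import pandas as pd
import yaml

from .simulate import MonthSpec, SimConfig
from .types import (
    BoatRecord,
    DailySurvey,
    LobsterRecord,
    ValidationError,
)

__all__ = [
    "NtzCalendar",
    "PriceSchedule",
    "ntz_status",
    "read_daily_surveys",
    "write_daily_surveys",
    "read_boat_records",
    "write_boat_records",
    "read_lobsters",
    "write_lobsters",
    "read_ntz_calendar",
    "write_ntz_calendar",
    "read_price_schedule",
    "write_price_schedule",
    "load_sim_config",
    "dump_sim_config",
    "attach_records",
]

SURVEY_COLUMNS = ["date", "site", "boats_at_sea", "boats_inactive"]
RECORD_COLUMNS = [
    "date",
    "site",
    "activity",
    "n_fishers",
    "n_pots",
    "n_lobsters",
    "total_weight_kg",
]
LOBSTER_COLUMNS = ["date", "species", "tl_mm", "cl_mm", "sex", "berried"]


@dataclass(frozen=True)
class NtzCalendar:
    """Inclusive (open_start, open_end) closure-lift intervals, sorted."""

    intervals: tuple[tuple[dt.date, dt.date], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.intervals:
            if end < start:
                raise ValidationError(f"interval {start}..{end} ends before it starts")
            if prev_end is not None and start <= prev_end:
                raise ValidationError(
                    "calendar intervals must be chronologically sorted and "
                    f"non-overlapping (at {start})"
                )
            prev_end = end


@dataclass(frozen=True)
class PriceSchedule:
    """(effective_from, price) steps with strictly increasing dates."""

    entries: tuple[tuple[dt.date, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("price schedule must be non-empty")
        prev = None
        for date, price in self.entries:
            if price <= 0:
                raise ValidationError(f"price must be > 0 (at {date})")
            if prev is not None and date <= prev:
                raise ValidationError("price dates must be strictly increasing")
            prev = date

    def price_at(self, date: dt.date) -> float:
        applicable = [p for d, p in self.entries if d <= date]
        if not applicable:
            raise ValidationError(f"no price effective on {date}")
        return applicable[-1]


def ntz_status(calendar: NtzCalendar, date: dt.date) -> str:
    """``"open"`` when the date falls inside any interval (ends inclusive)."""
    for start, end in calendar.intervals:
        if start <= date <= end:
            return "open"
    return "closed"


# ---------------------------------------------------------------------------
# CSV plumbing

def _parse_date(value: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"line {line}: unparseable date {value!r}") from exc


def _read_table(path, expected_columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    if list(df.columns) != expected_columns:
        raise ValidationError(
            f"{path}: expected columns {expected_columns}, got {list(df.columns)}"
        )
    return df

def _write_table(path, df: pd.DataFrame, metadata: dict | None) -> None:
    buf = io.StringIO()
    for key, value in (metadata or {}).items():
        buf.write(f"# {key}={value}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_daily_surveys(path) -> list[DailySurvey]:
    df = _read_table(path, SURVEY_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        line = i
        try:
            out.append(
                DailySurvey(
                    date=_parse_date(row.date, line),
                    site=row.site,
                    boats_at_sea=int(row.boats_at_sea),
                    boats_inactive=int(row.boats_inactive),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} line {line}: {exc}") from exc
    return out


def write_daily_surveys(path, surveys, metadata: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "date": s.date.isoformat(),
                "site": s.site,
                "boats_at_sea": s.boats_at_sea,
                "boats_inactive": s.boats_inactive,
            }
            for s in surveys
        ],
        columns=SURVEY_COLUMNS,
    )
    _write_table(path, df, metadata)


def read_boat_records(path) -> list[BoatRecord]:
    df = _read_table(path, RECORD_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                BoatRecord(
                    date=_parse_date(row.date, i),
                    site=row.site,
                    activity=row.activity,
                    n_fishers=int(row.n_fishers),
                    n_pots=int(row.n_pots),
                    n_lobsters=int(row.n_lobsters),
                    total_weight=float(row.total_weight_kg),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return out


def write_boat_records(path, records, metadata: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "date": r.date.isoformat(),
                "site": r.site,
                "activity": r.activity,
                "n_fishers": r.n_fishers,
                "n_pots": r.n_pots,
                "n_lobsters": r.n_lobsters,
                "total_weight_kg": repr(r.total_weight),
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )
    _write_table(path, df, metadata)


_BOOL = {"true": True, "false": False}


def read_lobsters(path) -> list[LobsterRecord]:
    df = _read_table(path, LOBSTER_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            berried = _BOOL.get(str(row.berried).lower())
            if berried is None:
                raise ValidationError(f"invalid berried flag {row.berried!r}")
            out.append(
                LobsterRecord(
                    date=_parse_date(row.date, i),
                    species=row.species,
                    tl=float(row.tl_mm),
                    cl=float(row.cl_mm),
                    sex=row.sex,
                    berried=berried,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return out


def write_lobsters(path, lobsters, metadata: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "date": lob.date.isoformat(),
                "species": lob.species,
                "tl_mm": repr(lob.tl),
                "cl_mm": repr(lob.cl),
                "sex": lob.sex,
                "berried": "true" if lob.berried else "false",
            }
            for lob in lobsters
        ],
        columns=LOBSTER_COLUMNS,
    )
    _write_table(path, df, metadata)


def read_ntz_calendar(path) -> NtzCalendar:
    df = _read_table(path, ["open_start", "open_end"])
    intervals = tuple(
        (_parse_date(r.open_start, i), _parse_date(r.open_end, i))
        for i, r in enumerate(df.itertuples(index=False), start=2)
    )
    return NtzCalendar(intervals=intervals)


def write_ntz_calendar(path, calendar: NtzCalendar, metadata: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {"open_start": s.isoformat(), "open_end": e.isoformat()}
            for s, e in calendar.intervals
        ],
        columns=["open_start", "open_end"],
    )
    _write_table(path, df, metadata)


def read_price_schedule(path) -> PriceSchedule:
    df = _read_table(path, ["effective_from", "price_mga_per_kg"])
    entries = tuple(
        (_parse_date(r.effective_from, i), float(r.price_mga_per_kg))
        for i, r in enumerate(df.itertuples(index=False), start=2)
    )
    return PriceSchedule(entries=entries)


def write_price_schedule(path, schedule: PriceSchedule, metadata: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {"effective_from": d.isoformat(), "price_mga_per_kg": p}
            for d, p in schedule.entries
        ],
        columns=["effective_from", "price_mga_per_kg"],
    )
    _write_table(path, df, metadata)


def attach_records(
    surveys: list[DailySurvey], records: list[BoatRecord]
) -> list[DailySurvey]:
    """Attach boat records to their (date, site) surveys, in place."""
    index: dict[tuple, DailySurvey] = {}
    for s in surveys:
        index[(s.date, s.site)] = s
        s.records = []
    for r in records:
        key = (r.date, r.site)
        if key in index:
            index[key].records.append(r)
    for s in surveys:
        if s.boats_at_sea < len(s.records):
            raise ValidationError(
                f"survey {s.date} at {s.site}: more sampled boats "
                f"({len(s.records)}) than boats at sea ({s.boats_at_sea})"
            )
    return surveys


# ---------------------------------------------------------------------------
# Simulation config files (YAML, key names exactly as SimConfig fields)

def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    try:
        months = [MonthSpec(**m) for m in raw.pop("months")]
        raw["tl_distribution"] = {
            sp: tuple(v) for sp, v in raw["tl_distribution"].items()
        }
        raw["cl_from_tl"] = {
            sp: {sex: tuple(v) for sex, v in by_sex.items()}
            for sp, by_sex in raw["cl_from_tl"].items()
        }
        raw["weight_from_tl"] = tuple(raw["weight_from_tl"])
        raw["hurdle_coefs_zero"] = tuple(raw["hurdle_coefs_zero"])
        raw["hurdle_coefs_count"] = tuple(raw["hurdle_coefs_count"])
        config = SimConfig(months=months, **raw)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: invalid config: {exc}") from exc
    config.validate()
    return config


def dump_sim_config(path, config: SimConfig) -> None:
    from dataclasses import asdict

    payload = asdict(config)
    payload["months"] = [asdict(m) for m in config.months]
    payload["tl_distribution"] = {k: list(v) for k, v in config.tl_distribution.items()}
    payload["cl_from_tl"] = {
        sp: {sex: list(v) for sex, v in by_sex.items()}
        for sp, by_sex in config.cl_from_tl.items()
    }
    payload["weight_from_tl"] = list(config.weight_from_tl)
    payload["hurdle_coefs_zero"] = list(config.hurdle_coefs_zero)
    payload["hurdle_coefs_count"] = list(config.hurdle_coefs_count)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
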