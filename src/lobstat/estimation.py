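"""Catch/effort raising estimator for monthly landings, effort and value.

The chain is L = E*C with E = D*B*F: days in month times boat activity
coefficient times fleet size, multiplied by mean sampled CPUE.  The daily
activity coefficient is B = A/T where A (active lobster-fishing boats) is
obtained by applying the sampled activity ratio to the full day's boat
count T (at sea plus inactive).  All chains are computed at full precision;
rounding is applied only when formatting reports.
"""

from __future__ import annotations

import statistics
from collections.abc import Iterable, Sequence

import pandas as pd

from .types import (
    BacObservation,
    BoatRecord,
    DailySurvey,
    MonthlyEstimate,
    ValidationError,
    month_key,
)

__all__ = [
    "UndefinedBacError",
    "MissingSampleError",
    "compute_bac",
    "monthly_bac",
    "monthly_fleet_size",
    "monthly_cpue",
    "monthly_estimate",
    "impute_month",
    "season_summary",
    "percent_change",
    "sample_adequacy",
    "build_monthly_table",
    "estimates_to_frame",
]


class UndefinedBacError(ValueError):
    """No boats counted: the activity coefficient A/T is undefined."""


class MissingSampleError(ValueError):
    """Boats went to sea but none were sampled, so the activity ratio is unknown."""


def compute_bac(survey: DailySurvey) -> BacObservation:
    """Daily boat-activity observation B = A/T from one landing-site survey.

    A is the sampled lobster-fishing ratio applied to the full count
    T = boats at sea + inactive boats; A is kept fractional.
    """
    total = survey.boats_at_sea + survey.boats_inactive
    if total <= 0:
        raise UndefinedBacError(
            f"survey {survey.date} at {survey.site}: no boats counted (T = 0)"
        )
    if survey.boats_at_sea == 0:
        ratio = 0.0
    else:
        if not survey.records:
            raise MissingSampleError(
                f"survey {survey.date} at {survey.site}: {survey.boats_at_sea} "
                "boats at sea but no sampled returns"
            )
        fishing = sum(1 for r in survey.records if r.activity == "lobster_fishing")
        ratio = fishing / len(survey.records)
    active = total * ratio
    return BacObservation(active=active, total=total, bac=active / total)


def monthly_bac(surveys: Iterable[DailySurvey], month: str) -> float:
    """Mean daily activity coefficient over Main-site surveys of a month.

    Only Main-site observations are used; the small, erratic second landing
    site is excluded from the fleet-wide coefficient by design.
    """
    bacs = [
        compute_bac(s).bac
        for s in surveys
        if s.site == "Main" and month_key(s.date) == month
    ]
    if not bacs:
        raise ValidationError(f"no Main-site surveys in month {month}")
    return statistics.fmean(bacs)


def monthly_fleet_size(
    surveys: Iterable[DailySurvey], month: str, upstream_boats: int = 5
) -> float:
    """Mean fleet size F: both-site daily boat counts plus the upstream boats.

    Only days on which both landing sites were surveyed qualify; the
    upstream boats (unobservable from either beach) are added as a constant.
    """
    by_date: dict = {}
    for s in surveys:
        if month_key(s.date) != month:
            continue
        by_date.setdefault(s.date, {})[s.site] = s.boats_at_sea + s.boats_inactive
    totals = [
        sites["Main"] + sites["Lodge"]
        for sites in by_date.values()
        if "Main" in sites and "Lodge" in sites
    ]
    if not totals:
        raise ValidationError(
            f"no day in month {month} on which both landing sites were surveyed"
        )
    return statistics.fmean(totals) + upstream_boats


def monthly_cpue(
    records: Iterable[BoatRecord], month: str, unit: str = "kg_per_boatday"
) -> float:
    """Mean sampled CPUE for a month over lobster-fishing boat records.

    Zero-catch lobster-fishing boats are included in the denominator (the
    zeros are true zeros).  ``unit`` selects kg per boatday (raising) or
    lobsters per boatday (modelling).
    """
    if unit not in ("kg_per_boatday", "lobsters_per_boatday"):
        raise ValidationError(f"unknown CPUE unit {unit!r}")
    values = [
        r.total_weight if unit == "kg_per_boatday" else r.n_lobsters
        for r in records
        if r.activity == "lobster_fishing" and month_key(r.date) == month
    ]
    if not values:
        raise ValidationError(f"no lobster-fishing boat records in month {month}")
    return statistics.fmean(values)


def monthly_estimate(
    days: int,
    bac: float,
    fleet: float,
    cpue: float,
    price: float,
    *,
    month: str = "",
    n_surveys: int | None = None,
    adequacy: dict | None = None,
) -> MonthlyEstimate:
    """Raise one month: E = D*B*F, L = E*C, V = L*P, at full precision."""
    if days < 28:
        raise ValidationError(f"days D must be >= 28, got {days}")
    if not (0 <= bac <= 1):
        raise ValidationError(f"B must lie in [0, 1], got {bac}")
    if not fleet > 0:
        raise ValidationError(f"F must be > 0, got {fleet}")
    if cpue < 0:
        raise ValidationError(f"C must be >= 0, got {cpue}")
    if price < 0:
        raise ValidationError(f"P must be >= 0, got {price}")
    effort = days * bac * fleet
    landings = effort * cpue
    value = landings * price
    return MonthlyEstimate(
        month=month,
        days=days,
        n_surveys=n_surveys,
        bac=bac,
        fleet=fleet,
        effort=effort,
        cpue=cpue,
        landings=landings,
        price=price,
        value=value,
        adequacy=adequacy,
    )


def impute_month(
    estimates: Iterable[MonthlyEstimate],
    target_month: str,
    donor_months: Sequence[str],
) -> float:
    """Impute a month's landings as the mean of the donor months' landings."""
    by_month = {e.month: e for e in estimates}
    missing = [m for m in donor_months if m not in by_month]
    if missing:
        raise ValidationError(f"donor months not estimated: {missing}")
    return statistics.fmean(by_month[m].landings for m in donor_months)


def season_summary(estimates: Iterable[MonthlyEstimate]) -> tuple[float, float]:
    """Total landings (kg) and value (MGA) across months, imputations included."""
    total_kg = 0.0
    total_value = 0.0
    for e in estimates:
        total_kg += e.landings
        total_value += e.value
    return total_kg, total_value


def percent_change(
    value: float, reference_values: Sequence[float], convention: str = "increase"
) -> float:
    """Percent change of ``value`` relative to the mean of the references.

    ``increase``: 100*(value - mean)/mean; ``ratio``: 100*value/mean.
    """
    if convention not in ("increase", "ratio"):
        raise ValidationError(f"unknown convention {convention!r}")
    if not reference_values:
        raise ValidationError("reference_values must be non-empty")
    ref = statistics.fmean(reference_values)
    if ref <= 0:
        raise ValidationError(f"reference mean must be > 0, got {ref}")
    if convention == "increase":
        return 100.0 * (value - ref) / ref
    return 100.0 * value / ref


def sample_adequacy(
    n: int,
    N: int,
    sample_sd: float,
    sample_mean: float,
    accuracy_threshold: float = 0.90,
) -> tuple[float, bool]:
    """Finite-population-corrected relative-SE accuracy of a sampled mean.

    accuracy = 1 - (sd/sqrt(n)) * sqrt((N-n)/(N-1)) / mean; the sample is
    adequate when accuracy meets the threshold (default 90%).
    """
    if not (1 <= n <= N):
        raise ValidationError(f"need 1 <= n <= N, got n={n}, N={N}")
    if sample_mean <= 0:
        raise ValidationError(f"sample mean must be > 0, got {sample_mean}")
    if sample_sd < 0:
        raise ValidationError(f"sample sd must be >= 0, got {sample_sd}")
    if N == 1:
        fpc = 0.0
    else:
        fpc = ((N - n) / (N - 1)) ** 0.5
    rse = (sample_sd / n**0.5) * fpc / sample_mean
    accuracy = 1.0 - rse
    return accuracy, accuracy >= accuracy_threshold


def build_monthly_table(
    surveys: Sequence[DailySurvey],
    records: Sequence[BoatRecord],
    months: Sequence[tuple[str, int, float]],
    upstream_boats: int = 5,
) -> list[MonthlyEstimate]:
    """Run the full raising chain for a list of (month, days, price) entries."""
    estimates = []
    for month, days, price in months:
        month_surveys = [s for s in surveys if month_key(s.date) == month]
        bac = monthly_bac(month_surveys, month)
        fleet = monthly_fleet_size(month_surveys, month, upstream_boats)
        cpue = monthly_cpue(records, month, unit="kg_per_boatday")
        n_surveys = len({s.date for s in month_surveys if s.site == "Main"})
        cpue_values = [
            r.total_weight
            for r in records
            if r.activity == "lobster_fishing" and month_key(r.date) == month
        ]
        n_c = len(cpue_values)
        mean_c = statistics.fmean(cpue_values)
        adequacy = None
        if mean_c > 0 and n_c >= 2:
            pop = max(n_c, round(days * bac * fleet)) or n_c
            acc, ok = sample_adequacy(
                n_c, max(pop, n_c), statistics.pstdev(cpue_values), mean_c
            )
            adequacy = {"cpue_accuracy": acc, "cpue_adequate": ok, "n": n_c}
        estimates.append(
            monthly_estimate(
                days,
                bac,
                fleet,
                cpue,
                price,
                month=month,
                n_surveys=n_surveys,
                adequacy=adequacy,
            )
        )
    return estimates


def estimates_to_frame(estimates: Sequence[MonthlyEstimate]) -> pd.DataFrame:
    """Monthly report table (one row per month: D, n, B, F, E, C, L, P, V).

    Display columns are rounded the way the printed table rounds (B and C to
    2 dp, E/L/V to integers); the underlying estimates stay unrounded.
    """
    rows = []
    for e in estimates:
        rows.append(
            {
                "month": e.month,
                "days": e.days,
                "n_surveys": e.n_surveys,
                "bac": None if e.bac is None else round(e.bac, 2),
                "fleet": None if e.fleet is None else round(e.fleet),
                "effort_boatdays": None if e.effort is None else round(e.effort),
                "cpue_kg_boatday": None if e.cpue is None else round(e.cpue, 2),
                "landings_kg": round(e.landings),
                "price_mga_kg": e.price,
                "value_mga": round(e.value),
                "imputed": e.imputed,
            }
        )
    return pd.DataFrame(rows)
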