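"""Core record types shared across the survey, modelling and composition modules.

All records are plain dataclasses validated on construction; dates are
``datetime.date`` and months are addressed by ``"YYYY-MM"`` keys.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

SPINY_SPECIES = ("P_homarus", "P_longipes", "P_ornatus", "P_penicillatus")
SLIPPER_SPECIES = ("S_squammosus", "P_antarticus", "A_regalis")
SPECIES = SPINY_SPECIES + SLIPPER_SPECIES
DOMINANT_SPECIES = ("P_homarus", "P_longipes")

SITES = ("Main", "Lodge")
ACTIVITIES = ("lobster_fishing", "other")
SEXES = ("male", "female")


class ValidationError(ValueError):
    """A record or configuration violates one of its invariants."""


def month_key(date: dt.date) -> str:
    """Return the ``YYYY-MM`` month identifier of a date."""
    return f"{date.year:04d}-{date.month:02d}"


@dataclass(frozen=True)
class BoatRecord:
    """One sampled boat-day: activity, crew, gear and catch."""

    date: dt.date
    site: str
    activity: str
    n_fishers: int
    n_pots: int
    n_lobsters: int
    total_weight: float  # kg

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"site must be one of {SITES}, got {self.site!r}")
        if self.activity not in ACTIVITIES:
            raise ValidationError(
                f"activity must be one of {ACTIVITIES}, got {self.activity!r}"
            )
        if self.n_fishers < 0 or self.n_pots < 0 or self.n_lobsters < 0:
            raise ValidationError("n_fishers, n_pots and n_lobsters must be >= 0")
        if self.total_weight < 0:
            raise ValidationError("total_weight must be >= 0")
        if (self.n_lobsters == 0) != (self.total_weight == 0):
            raise ValidationError(
                "n_lobsters == 0 if and only if total_weight == 0 "
                f"(got n_lobsters={self.n_lobsters}, total_weight={self.total_weight})"
            )


@dataclass
class DailySurvey:
    """One landing-site visit: boats at sea, inactive boats, sampled returns."""

    date: dt.date
    site: str
    boats_at_sea: int
    boats_inactive: int
    records: list[BoatRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"site must be one of {SITES}, got {self.site!r}")
        if self.boats_at_sea < 0 or self.boats_inactive < 0:
            raise ValidationError("boat counts must be >= 0")
        if self.boats_at_sea < len(self.records):
            raise ValidationError(
                f"boats_at_sea ({self.boats_at_sea}) < number of sampled "
                f"returning boats ({len(self.records)})"
            )


@dataclass(frozen=True)
class LobsterRecord:
    """One measured individual from the catch-composition survey."""

    date: dt.date
    species: str
    tl: float  # total length, mm
    cl: float  # carapace length, mm
    sex: str
    berried: bool = False

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"species must be one of {SPECIES}, got {self.species!r}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (self.tl > self.cl > 0):
            raise ValidationError(
                f"lengths must satisfy TL > CL > 0 (got TL={self.tl}, CL={self.cl})"
            )
        if self.berried and self.sex != "female":
            raise ValidationError("berried implies female")


@dataclass(frozen=True)
class BacObservation:
    """One day's boat-activity observation: A active of T total boats."""

    active: float  # A — may be fractional after applying the sampled ratio
    total: int  # T
    bac: float  # B = A / T

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValidationError("total boats T must be > 0")
        if not (0 <= self.active <= self.total):
            raise ValidationError(
                f"active boats A must lie in [0, T] (A={self.active}, T={self.total})"
            )


@dataclass
class MonthlyEstimate:
    """One month of the raising estimator: E = D*B*F, L = E*C, V = L*P."""

    month: str  # "YYYY-MM"
    days: int  # D
    n_surveys: int | None  # survey occasions (metadata only)
    bac: float | None  # B
    fleet: float | None  # F, boats
    effort: float | None  # E, boatdays
    cpue: float | None  # C, kg per boatday
    landings: float  # L, kg
    price: float  # P, MGA per kg
    value: float  # V, MGA
    imputed: bool = False
    adequacy: dict | None = None

    def __post_init__(self) -> None:
        if self.bac is not None and not (0 <= self.bac <= 1):
            raise ValidationError(f"B must lie in [0, 1], got {self.bac}")
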