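"""Catch composition, reproduction, size structure and earnings statistics."""

from __future__ import annotations

import math
import statistics
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kstwobign

from .types import (
    BoatRecord,
    DOMINANT_SPECIES,
    LobsterRecord,
    SLIPPER_SPECIES,
    SPINY_SPECIES,
    ValidationError,
    month_key,
)

__all__ = [
    "KsResult",
    "TlClFit",
    "composition_by_month",
    "berried_proportion",
    "proportion_under_mls",
    "ks_two_sample",
    "size_density",
    "tl_cl_fit",
    "median_daily_earnings",
    "species_group",
]

MLS_MM = 200.0

COMPOSITION_GROUPS = ("P_homarus", "P_longipes", "other_spiny", "other_slipper")


def species_group(species: str) -> str:
    """Reporting group: dominant species stay separate, the rest are pooled."""
    if species in DOMINANT_SPECIES:
        return species
    if species in SPINY_SPECIES:
        return "other_spiny"
    if species in SLIPPER_SPECIES:
        return "other_slipper"
    raise ValidationError(f"unknown species {species!r}")


@dataclass(frozen=True)
class KsResult:
    D: float
    p_value: float
    n1: int
    n2: int


@dataclass(frozen=True)
class TlClFit:
    slope: float
    intercept: float
    resid_sd: float
    n: int

    def predict(self, cl: float) -> float:
        return self.slope * cl + self.intercept


def composition_by_month(lobsters: Iterable[LobsterRecord]) -> pd.DataFrame:
    """Per-month proportions of the reporting groups (rows sum to 1)."""
    counts: dict[str, dict[str, int]] = {}
    for lob in lobsters:
        mk = month_key(lob.date)
        g = species_group(lob.species)
        counts.setdefault(mk, {g2: 0 for g2 in COMPOSITION_GROUPS})[g] += 1
    if not counts:
        raise ValidationError("no lobster records")
    rows = []
    for mk in sorted(counts):
        total = sum(counts[mk].values())
        rows.append(
            {"month": mk, **{g: counts[mk][g] / total for g in COMPOSITION_GROUPS}}
        )
    return pd.DataFrame(rows).set_index("month")


def berried_proportion(
    lobsters: Iterable[LobsterRecord], species: str, month: str
) -> float:
    """Berried females over all females of the species-month."""
    females = [
        lob
        for lob in lobsters
        if lob.species == species and lob.sex == "female" and month_key(lob.date) == month
    ]
    if not females:
        raise ValidationError(
            f"no females of {species} in month {month}: proportion undefined"
        )
    return sum(1 for lob in females if lob.berried) / len(females)


def proportion_under_mls(
    lobsters: Iterable[LobsterRecord], mls: float = MLS_MM
) -> float:
    """Fraction of individuals with total length strictly below the MLS."""
    tls = [lob.tl for lob in lobsters]
    if not tls:
        raise ValidationError("no lobster records")
    return sum(1 for tl in tls if tl < mls) / len(tls)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test on pooled evaluation points.

    D is the largest ECDF gap over the pooled unique sample points (ties
    handled by construction); the p-value is the asymptotic Kolmogorov
    distribution at sqrt(n1*n2/(n1+n2)) * D.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(x, pooled, side="right") / n1
    fy = np.searchsorted(y, pooled, side="right") / n2
    d = float(np.max(np.abs(fx - fy)))
    if d == 0.0:
        p = 1.0
    else:
        en = n1 * n2 / (n1 + n2)
        p = float(np.clip(kstwobign.sf(math.sqrt(en) * d), 0.0, 1.0))
    return KsResult(D=d, p_value=p, n1=n1, n2=n2)


def size_density(
    tls: Sequence[float],
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
    bin_width: float = 10.0,
) -> dict:
    """Gaussian KDE plus a left-closed histogram (bins anchored at 0).

    ``bandwidth`` is the kernel standard deviation (the R convention used in
    the figure captions); Silverman's rule is the default.
    """
    x = np.asarray(tls, dtype=float)
    if len(x) < 2:
        raise ValidationError("need at least 2 values for a density estimate")
    if bandwidth is None:
        sd = float(np.std(x, ddof=1))
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = 0.9 * spread * len(x) ** (-0.2)
    if not bandwidth > 0:
        raise ValidationError(f"bandwidth must be > 0, got {bandwidth}")
    if grid is None:
        lo = math.floor((x.min() - 4 * bandwidth) / bin_width) * bin_width
        hi = math.ceil((x.max() + 4 * bandwidth) / bin_width) * bin_width
        grid = np.linspace(lo, hi, 512)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - x[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1) / (
        len(x) * bandwidth * math.sqrt(2 * math.pi)
    )
    # left-closed bins anchored at 0; the final edge exceeds the maximum, so
    # np.histogram's closed last bin never captures a boundary value
    first = max(0.0, math.floor(x.min() / bin_width) * bin_width)
    last = math.floor(x.max() / bin_width) * bin_width + bin_width
    edges = np.arange(first, last + bin_width / 2, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    return {
        "grid": grid,
        "density": density,
        "bandwidth": float(bandwidth),
        "bin_edges": edges,
        "counts": counts,
    }


def tl_cl_fit(
    lobsters: Iterable[LobsterRecord], species: str, sex: str
) -> TlClFit:
    """OLS regression TL ~ CL within one species-sex group."""
    pairs = [
        (lob.cl, lob.tl)
        for lob in lobsters
        if lob.species == species and lob.sex == sex
    ]
    if len(pairs) < 3:
        raise ValidationError(
            f"need >= 3 records for {species}/{sex}, got {len(pairs)}"
        )
    cl = np.array([p[0] for p in pairs])
    tl = np.array([p[1] for p in pairs])
    if np.ptp(cl) == 0:
        raise ValidationError(f"degenerate regressor: CL constant for {species}/{sex}")
    slope, intercept = np.polyfit(cl, tl, 1)
    resid = tl - (slope * cl + intercept)
    dof = max(len(pairs) - 2, 1)
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return TlClFit(
        slope=float(slope), intercept=float(intercept), resid_sd=resid_sd, n=len(pairs)
    )


def median_daily_earnings(
    records: Iterable[BoatRecord], price: float
) -> tuple[float, float]:
    """Median per-fisher daily catch (kg) and the earnings it implies (MGA)."""
    per_fisher = []
    for r in records:
        if r.activity != "lobster_fishing":
            continue
        if r.n_fishers < 1:
            raise ValidationError(
                f"record {r.date} at {r.site}: lobster-fishing boat with no fishers"
            )
        per_fisher.append(r.total_weight / r.n_fishers)
    if not per_fisher:
        raise ValidationError("no lobster-fishing records")
    med = statistics.median(per_fisher)
    return med, med * price
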