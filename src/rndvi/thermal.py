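"""Thermal time: growing degree days, their accumulation, and the
relative season clock.

Crop development is driven by accumulated heat rather than calendar
time, so the pipeline converts dates to accumulated growing degree days
(AGDD, degree-days above a base temperature) and then to relative AGDD,

    RAGDD_i = AGDD_i / AGDD_h,

where AGDD_h is the total from transplanting to harvest. RAGDD is a
dimensionless [0, 1] season clock that transfers across sites and
years; it is the sole driving variable of the canopy-NDVI dynamic
models downstream.

Daily GDD uses the simple-average method, max(0, (Tmin+Tmax)/2 - Tbase),
with Tbase defaulting to 10 degrees C, the dominant convention for rice.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

from .types import PlotInfo, WeatherSeries

DEFAULT_TBASE_C = 10.0


def daily_gdd(tmin: float, tmax: float, tbase: float = DEFAULT_TBASE_C) -> float:
    """Growing degree days for one day, simple-average method.

    Returns max(0, (tmin + tmax)/2 - tbase); negative contributions are
    clamped to zero (cold days do not reverse development).
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    return max(0.0, 0.5 * (tmin + tmax) - tbase)


@dataclass(frozen=True)
class ThermalEntry:
    date: datetime.date
    dat: int
    agdd: float
    ragdd: float


@dataclass
class ThermalSeries:
    """Per-date accumulated and relative thermal time for one plot season.

    Covers every calendar day from transplanting (DAT 0) through
    harvest; agdd_h is the accumulated total at harvest and ragdd at
    harvest is exactly 1.
    """

    plot_id: str
    entries: list[ThermalEntry]
    agdd_h: float

    def __post_init__(self) -> None:
        self._by_dat = {e.dat: e for e in self.entries}

    def agdd_at(self, dat: int) -> float:
        return self._by_dat[dat].agdd

    def ragdd_at(self, dat: int) -> float:
        return self._by_dat[dat].ragdd

    def __len__(self) -> int:
        return len(self.entries)


def accumulate(
    weather: WeatherSeries,
    plot: PlotInfo,
    tbase: float = DEFAULT_TBASE_C,
    include_transplant_day: bool = True,
) -> ThermalSeries:
    """Accumulate daily GDD over a plot's season and fill the RAGDD clock.

    The weather series must cover every day from transplanting through
    harvest with no gaps; a missing day is a hard error because AGDD is
    an exact cumulative sum (no interpolation is attempted). With
    ``include_transplant_day`` (the default) the transplanting day's own
    GDD is counted, so AGDD on DAT i sums days 0..i; otherwise days 1..i.
    """
    by_date = weather.by_date()
    n_days = plot.season_length
    entries: list[ThermalEntry] = []
    agdd = 0.0
    agdds: list[float] = []
    for dat in range(n_days + 1):
        day = plot.transplant_date + datetime.timedelta(days=dat)
        rec = by_date.get(day)
        if rec is None:
            raise ValueError(
                f"plot {plot.plot_id}: weather gap at {day} (DAT {dat}) inside "
                f"the season [{plot.transplant_date}, {plot.harvest_date}]"
            )
        if dat > 0 or include_transplant_day:
            agdd += daily_gdd(rec.tmin, rec.tmax, tbase)
        agdds.append(agdd)
    agdd_h = agdds[-1]
    if agdd_h <= 0:
        raise ValueError(
            f"plot {plot.plot_id}: zero accumulated thermal time over the season"
        )
    for dat, a in enumerate(agdds):
        day = plot.transplant_date + datetime.timedelta(days=dat)
        entries.append(ThermalEntry(date=day, dat=dat, agdd=a, ragdd=a / agdd_h))
    return ThermalSeries(plot_id=plot.plot_id, entries=entries, agdd_h=agdd_h)
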