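"""Domain types shared by every pipeline stage.

The pipeline works with three kinds of raw records: daily weather
(min/max air temperature), per-plot canopy NDVI readings from an
active-optical proximal sensor, and plot metadata (cultivar, nitrogen
rate, transplanting/harvest dates, grain yield). Types validate their
own invariants on construction so downstream stages can assume clean
data.
"""

from __future__ import annotations

import datetime
import enum
import math
from dataclasses import dataclass, field


class CultivarType(str, enum.Enum):
    """The two rice subspecies groups compared throughout the analysis."""

    JAPONICA = "Japonica"
    INDICA = "Indica"


class YieldLevel(str, enum.Enum):
    """Production level of a plot, assigned from grain yield (t/ha).

    low: yield <= 8.25; middle: 8.25 < yield < 10.5; high: yield >= 10.5.
    """

    LOW = "low"
    MIDDLE = "middle"
    HIGH = "high"


@dataclass(frozen=True)
class WeatherRecord:
    """One day of air temperature extremes (degrees Celsius)."""

    date: datetime.date
    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tmin) and math.isfinite(self.tmax)):
            raise ValueError(f"non-finite temperature on {self.date}")
        if self.tmax < self.tmin:
            raise ValueError(
                f"tmax ({self.tmax}) < tmin ({self.tmin}) on {self.date}"
            )


@dataclass
class WeatherSeries:
    """Date-sorted daily weather for one site-year.

    Dates must be strictly increasing; duplicates are rejected. Gap
    checking is deferred to thermal-time accumulation, which knows the
    season window that must be covered.
    """

    records: list[WeatherRecord]

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.date)
        for prev, cur in zip(self.records, self.records[1:]):
            if cur.date == prev.date:
                raise ValueError(f"duplicate weather date {cur.date}")

    def __len__(self) -> int:
        return len(self.records)

    def by_date(self) -> dict[datetime.date, WeatherRecord]:
        return {r.date: r for r in self.records}


@dataclass
class PlotInfo:
    """Metadata for one experimental plot.

    grain_yield is optional until harvest; n_rate is elemental N in
    kg/ha. The transplanting day is day 0 of the season clock.
    """

    plot_id: str
    cultivar: str
    cultivar_type: CultivarType
    n_rate: float
    transplant_date: datetime.date
    harvest_date: datetime.date
    grain_yield: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.cultivar_type, str) and not isinstance(
            self.cultivar_type, CultivarType
        ):
            self.cultivar_type = CultivarType(self.cultivar_type)
        if self.n_rate < 0:
            raise ValueError(f"plot {self.plot_id}: negative N rate {self.n_rate}")
        if self.harvest_date <= self.transplant_date:
            raise ValueError(
                f"plot {self.plot_id}: harvest_date {self.harvest_date} not after "
                f"transplant_date {self.transplant_date}"
            )
        if self.grain_yield is not None and self.grain_yield < 0:
            raise ValueError(
                f"plot {self.plot_id}: negative grain yield {self.grain_yield}"
            )

    @property
    def season_length(self) -> int:
        """Days from transplanting (day 0) to harvest, inclusive of both."""
        return (self.harvest_date - self.transplant_date).days


@dataclass(frozen=True)
class NdviObservation:
    """One averaged canopy NDVI reading for one plot on one date.

    dat is days after transplanting with the transplanting day itself
    as DAT 0.
    """

    plot_id: str
    date: datetime.date
    dat: int
    ndvi: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ndvi):
            raise ValueError(f"plot {self.plot_id} {self.date}: non-finite NDVI")
        if not -1.0 <= self.ndvi <= 1.0:
            raise ValueError(
                f"plot {self.plot_id} {self.date}: NDVI {self.ndvi} outside [-1, 1]"
            )
        if self.dat < 0:
            raise ValueError(
                f"plot {self.plot_id} {self.date}: observation precedes transplanting"
                f" (dat={self.dat})"
            )


@dataclass
class ObservationSeries:
    """Time-ordered NDVI observations for one plot, joined to its metadata."""

    plot: PlotInfo
    observations: list[NdviObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for obs in self.observations:
            if obs.plot_id != self.plot.plot_id:
                raise ValueError(
                    f"observation plot_id {obs.plot_id!r} does not match "
                    f"series plot {self.plot.plot_id!r}"
                )
        for prev, cur in zip(self.observations, self.observations[1:]):
            if cur.date <= prev.date:
                raise ValueError(
                    f"plot {self.plot.plot_id}: observation dates not strictly "
                    f"increasing at {cur.date}"
                )

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def dats(self) -> list[int]:
        return [o.dat for o in self.observations]

    @property
    def ndvis(self) -> list[float]:
        return [o.ndvi for o in self.observations]


def assign_yield_level(grain_yield: float) -> YieldLevel:
    """Classify a grain yield (t/ha) into low/middle/high production level.

    Boundaries follow the published grouping for Jiangsu rice: a plot at
    exactly 8.25 t/ha is low; at exactly 10.5 t/ha it is high.
    """
    if grain_yield < 0 or not math.isfinite(grain_yield):
        raise ValueError(f"invalid grain yield {grain_yield}")
    if grain_yield <= 8.25:
        return YieldLevel.LOW
    if grain_yield >= 10.5:
        return YieldLevel.HIGH
    return YieldLevel.MIDDLE
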