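"""Synthetic multi-plot rice experiments with the statistical structure
the analysis assumes.

No canopy-sensor dataset ships with this package, so every pipeline
stage is exercised against generated data: sinusoidal-season weather,
double-logistic NDVI trajectories scaled by published per-treatment
seasonal maxima with additive Gaussian sensor noise, and a full
factorial design (cultivars x N rates x replicates) emulating the
model-building experiments (2 cultivars x 6 N rates x 3 replicates,
~25-30 sampling dates over a 133-156 day season).

Seeding: one master seed per design; each plot derives its own stream
by stable hashing of its plot id, so adding a plot never perturbs the
data of the others.
"""

from __future__ import annotations

import datetime
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as rio
from .curves import CurveSpec, eval_curve
from .reference import (
    CULTIVAR_TYPE,
    GROUP_PARAMS,
    NDVI_MAX_BY_CULTIVAR_N,
    SEASON_LENGTH,
    YIELD_BY_CULTIVAR_N,
)
from .thermal import ThermalSeries, accumulate
from .types import (
    CultivarType,
    NdviObservation,
    ObservationSeries,
    PlotInfo,
    WeatherRecord,
    WeatherSeries,
    YieldLevel,
    assign_yield_level,
)

#: yield bands (t/ha) of the three production levels; jittered yields
#: are clipped to their design level's band so grouping is stable
_LEVEL_BANDS: dict[YieldLevel, tuple[float, float]] = {
    YieldLevel.LOW: (0.0, 8.25),
    YieldLevel.MIDDLE: (8.25 + 1e-6, 10.5 - 1e-6),
    YieldLevel.HIGH: (10.5, 99.0),
}


def _plot_stream_seed(master_seed: int, plot_id: str, salt: int = 0) -> list[int]:
    return [int(master_seed), zlib.crc32(plot_id.encode("utf-8")), salt]


def gen_weather(
    seed: int,
    n_days: int,
    mean_t: float = 25.0,
    amplitude: float = 4.0,
    daily_sd: float = 1.5,
    diurnal_range: float = 10.0,
    start_date: datetime.date = datetime.date(2014, 6, 17),
) -> WeatherSeries:
    """Daily weather with a half-sine seasonal mean and Gaussian jitter.

    The daily mean follows mean_t + amplitude*sin(pi*d/n) (warm
    mid-season, cooling toward harvest) plus N(0, daily_sd) jitter;
    tmin/tmax sit half the diurnal range below/above it, so tmax >= tmin
    holds by construction. Reproducible per seed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    d = np.arange(n_days)
    mean = mean_t + amplitude * np.sin(np.pi * d / max(n_days - 1, 1))
    jitter = rng.normal(0.0, daily_sd, n_days) if daily_sd > 0 else np.zeros(n_days)
    half = abs(diurnal_range) / 2.0
    records = [
        WeatherRecord(
            date=start_date + datetime.timedelta(days=int(i)),
            tmin=float(mean[i] + jitter[i] - half),
            tmax=float(mean[i] + jitter[i] + half),
        )
        for i in d
    ]
    return WeatherSeries(records)


def gen_plot_trajectory(
    plot: PlotInfo,
    thermal: ThermalSeries,
    truth: CurveSpec,
    ndvi_max: float,
    sampling_dats: list[int],
    noise_sd: float = 0.015,
    seed=0,
) -> ObservationSeries:
    """One plot's NDVI series from a generating curve plus sensor noise.

    NDVI(dat) = ndvi_max * truth(RAGDD(dat)) + N(0, noise_sd), truncated
    to [0, 1]. Sampling dates must fall inside the plot's season.
    """
    rng = np.random.default_rng(seed)
    obs = []
    for dat in sampling_dats:
        if dat < 0 or dat > plot.season_length:
            raise ValueError(
                f"plot {plot.plot_id}: sampling DAT {dat} outside season "
                f"[0, {plot.season_length}]"
            )
        ndvi = ndvi_max * eval_curve(truth, thermal.ragdd_at(dat))
        if noise_sd > 0:
            ndvi += rng.normal(0.0, noise_sd)
        ndvi = float(np.clip(ndvi, 0.0, 1.0))
        obs.append(
            NdviObservation(
                plot_id=plot.plot_id,
                date=plot.transplant_date + datetime.timedelta(days=int(dat)),
                dat=int(dat),
                ndvi=ndvi,
            )
        )
    return ObservationSeries(plot=plot, observations=obs)


@dataclass(frozen=True)
class CultivarDesign:
    """One cultivar's amplitudes and yields across the N-rate ladder."""

    name: str
    cultivar_type: CultivarType
    season_length: int
    ndvi_max: dict[int, float]
    grain_yield: dict[int, float]

    def __post_init__(self) -> None:
        if self.season_length < 60:
            raise ValueError(
                f"{self.name}: season_length {self.season_length} < 60 days"
            )


@dataclass(frozen=True)
class ExperimentDesign:
    """A factorial canopy-sensing experiment: cultivars x N rates x reps."""

    cultivars: tuple[CultivarDesign, ...]
    n_rates: tuple[int, ...] = (0, 75, 150, 225, 300, 375)
    replicates: int = 3
    transplant_date: datetime.date = datetime.date(2014, 6, 17)
    noise_sd: float = 0.015
    seed: int = 0
    sampling_step: int = 5
    first_sampling_dat: int = 6
    yield_jitter_sd: float = 0.1
    truth: dict[tuple[CultivarType, YieldLevel], CurveSpec] = field(
        default_factory=lambda: dict(GROUP_PARAMS)
    )
    weather_mean_t: float = 25.0
    weather_amplitude: float = 4.0
    weather_daily_sd: float = 1.5
    weather_diurnal_range: float = 10.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for c in self.cultivars:
            missing = [n for n in self.n_rates if n not in c.ndvi_max]
            if missing:
                raise ValueError(f"{c.name}: no ndvi_max for N rate(s) {missing}")

    def with_seed(self, seed: int) -> "ExperimentDesign":
        return replace(self, seed=seed)


def default_design(seed: int = 0, noise_sd: float = 0.015) -> ExperimentDesign:
    """The default two-cultivar design: WYJ24 (Japonica, 156 d season)
    and YLY1 (Indica, 133 d), six N rates, three replicate plots."""
    cultivars = tuple(
        CultivarDesign(
            name=name,
            cultivar_type=CULTIVAR_TYPE[name],
            season_length=SEASON_LENGTH[name],
            ndvi_max=dict(NDVI_MAX_BY_CULTIVAR_N[name]),
            grain_yield=dict(YIELD_BY_CULTIVAR_N[name]),
        )
        for name in ("WYJ24", "YLY1")
    )
    return ExperimentDesign(cultivars=cultivars, seed=seed, noise_sd=noise_sd)


def gen_experiment(
    design: ExperimentDesign, outdir: str | Path | None = None
) -> tuple[WeatherSeries, list[PlotInfo], list[ObservationSeries]]:
    """Generate a full experiment; optionally write it as CSV files.

    Each plot's grain yield is the design's per-N-rate yield plus small
    jitter clipped to stay inside the design level's band, so yield
    grouping reproduces the intended low/middle/high partition. The
    generating curve for a plot is the design truth for its (cultivar
    type, yield level). When ``outdir`` is given, weather.csv,
    metadata.csv and sensor.csv are written there in the formats the
    readers accept; output is byte-identical for identical design+seed.
    """
    max_season = max(c.season_length for c in design.cultivars)
    weather = gen_weather(
        seed=design.seed,
        n_days=max_season + 1,
        mean_t=design.weather_mean_t,
        amplitude=design.weather_amplitude,
        daily_sd=design.weather_daily_sd,
        diurnal_range=design.weather_diurnal_range,
        start_date=design.transplant_date,
    )
    plots: list[PlotInfo] = []
    series_list: list[ObservationSeries] = []
    for cult in design.cultivars:
        sampling_dats = list(
            range(
                design.first_sampling_dat,
                cult.season_length - 4,
                design.sampling_step,
            )
        )
        for n_rate in design.n_rates:
            y0 = cult.grain_yield[n_rate]
            level = assign_yield_level(y0)
            lo, hi = _LEVEL_BANDS[level]
            truth = design.truth[(cult.cultivar_type, level)]
            for rep in range(1, design.replicates + 1):
                plot_id = f"{cult.name}-N{n_rate}-R{rep}"
                yrng = np.random.default_rng(
                    _plot_stream_seed(design.seed, plot_id, salt=1)
                )
                gy = float(
                    np.clip(y0 + yrng.normal(0.0, design.yield_jitter_sd), lo, hi)
                )
                plot = PlotInfo(
                    plot_id=plot_id,
                    cultivar=cult.name,
                    cultivar_type=cult.cultivar_type,
                    n_rate=float(n_rate),
                    transplant_date=design.transplant_date,
                    harvest_date=design.transplant_date
                    + datetime.timedelta(days=cult.season_length),
                    grain_yield=gy,
                )
                thermal = accumulate(weather, plot)
                series = gen_plot_trajectory(
                    plot=plot,
                    thermal=thermal,
                    truth=truth,
                    ndvi_max=cult.ndvi_max[n_rate],
                    sampling_dats=sampling_dats,
                    noise_sd=design.noise_sd,
                    seed=_plot_stream_seed(design.seed, plot_id, salt=0),
                )
                plots.append(plot)
                series_list.append(series)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rio.write_weather(weather, outdir / "weather.csv")
        rio.write_metadata(plots, outdir / "metadata.csv")
        rio.write_sensor_log(series_list, outdir / "sensor.csv")
    return weather, plots, series_list
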