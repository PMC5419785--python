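"""CSV readers and writers for weather, sensor logs, and plot metadata.

File conventions: comma-separated UTF-8 with a header row and ISO-8601
dates. The sensor log may contain replicate readings for the same plot
and date (the proximal sensor is passed over several rows of plants);
replicates are averaged into one observation, matching how the field
protocol reports NDVI.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import pandas as pd

from .types import (
    CultivarType,
    NdviObservation,
    ObservationSeries,
    PlotInfo,
    WeatherRecord,
    WeatherSeries,
)

WEATHER_COLUMNS = ["date", "tmin_c", "tmax_c"]
SENSOR_COLUMNS = ["plot_id", "date", "ndvi"]
METADATA_COLUMNS = [
    "plot_id",
    "cultivar",
    "cultivar_type",
    "n_rate",
    "transplant_date",
    "harvest_date",
    "grain_yield",
]


class InputError(ValueError):
    """A malformed or inconsistent input file."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")


def _parse_date(value, path, row: int) -> datetime.date:
    try:
        return datetime.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise InputError(f"{path} row {row}: unparsable date {value!r}") from exc


def read_weather(path) -> WeatherSeries:
    """Read a daily weather CSV (date, tmin_c, tmax_c) into a sorted series."""
    df = pd.read_csv(path)
    _require_columns(df, WEATHER_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        date = _parse_date(row["date"], path, i)
        try:
            rec = WeatherRecord(
                date=date, tmin=float(row["tmin_c"]), tmax=float(row["tmax_c"])
            )
        except ValueError as exc:
            raise InputError(f"{path} row {i}: {exc}") from exc
        records.append(rec)
    try:
        return WeatherSeries(records)
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_weather(series: WeatherSeries, path) -> None:
    df = pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in series.records],
            "tmin_c": [r.tmin for r in series.records],
            "tmax_c": [r.tmax for r in series.records],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_metadata(path) -> dict[str, PlotInfo]:
    """Read the plot metadata CSV into a mapping plot_id -> PlotInfo."""
    df = pd.read_csv(path)
    _require_columns(df, METADATA_COLUMNS, path)
    plots: dict[str, PlotInfo] = {}
    for i, row in df.iterrows():
        plot_id = str(row["plot_id"])
        if plot_id in plots:
            raise InputError(f"{path} row {i}: duplicate plot_id {plot_id!r}")
        raw_yield = row["grain_yield"]
        grain_yield = None if pd.isna(raw_yield) else float(raw_yield)
        try:
            plots[plot_id] = PlotInfo(
                plot_id=plot_id,
                cultivar=str(row["cultivar"]),
                cultivar_type=CultivarType(str(row["cultivar_type"])),
                n_rate=float(row["n_rate"]),
                transplant_date=_parse_date(row["transplant_date"], path, i),
                harvest_date=_parse_date(row["harvest_date"], path, i),
                grain_yield=grain_yield,
            )
        except ValueError as exc:
            raise InputError(f"{path} row {i}: {exc}") from exc
    return plots


def write_metadata(plots: list[PlotInfo], path) -> None:
    df = pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "cultivar": [p.cultivar for p in plots],
            "cultivar_type": [p.cultivar_type.value for p in plots],
            "n_rate": [p.n_rate for p in plots],
            "transplant_date": [p.transplant_date.isoformat() for p in plots],
            "harvest_date": [p.harvest_date.isoformat() for p in plots],
            "grain_yield": [p.grain_yield for p in plots],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_sensor_log(path, metadata_path) -> list[ObservationSeries]:
    """Read sensor readings and join them to plot metadata.

    Replicate rows sharing (plot_id, date) are averaged into a single
    observation; DAT is computed from the plot's transplanting date
    (transplanting day = DAT 0). A reading for a plot absent from the
    metadata, dated before transplanting, or outside [-1, 1] is an error.
    """
    plots = read_metadata(metadata_path)
    df = pd.read_csv(path)
    _require_columns(df, SENSOR_COLUMNS, path)
    df = df.copy()
    df["plot_id"] = df["plot_id"].astype(str)
    unknown = sorted(set(df["plot_id"]) - set(plots))
    if unknown:
        raise InputError(f"{path}: plot_id(s) {unknown} absent from metadata")
    df["_date"] = [
        _parse_date(v, path, i) for i, v in zip(df.index, df["date"])
    ]
    bad = df[(df["ndvi"] < -1) | (df["ndvi"] > 1) | df["ndvi"].isna()]
    if len(bad):
        raise InputError(
            f"{path}: NDVI outside [-1, 1] for plot(s) "
            f"{sorted(bad['plot_id'].unique())}"
        )
    averaged = (
        df.groupby(["plot_id", "_date"], sort=True)["ndvi"].mean().reset_index()
    )
    series: list[ObservationSeries] = []
    for plot_id in sorted(averaged["plot_id"].unique()):
        plot = plots[plot_id]
        sub = averaged[averaged["plot_id"] == plot_id].sort_values("_date")
        obs = []
        for _, row in sub.iterrows():
            dat = (row["_date"] - plot.transplant_date).days
            if dat < 0:
                raise InputError(
                    f"{path}: plot {plot_id} reading on {row['_date']} precedes "
                    f"transplanting ({plot.transplant_date})"
                )
            obs.append(
                NdviObservation(
                    plot_id=plot_id,
                    date=row["_date"],
                    dat=dat,
                    ndvi=float(row["ndvi"]),
                )
            )
        series.append(ObservationSeries(plot=plot, observations=obs))
    return series


def write_sensor_log(series_list: list[ObservationSeries], path) -> None:
    rows = [
        {"plot_id": o.plot_id, "date": o.date.isoformat(), "ndvi": o.ndvi}
        for s in series_list
        for o in s.observations
    ]
    pd.DataFrame(rows, columns=SENSOR_COLUMNS).to_csv(
        path, index=False, float_format="%.6f"
    )
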