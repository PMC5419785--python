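import datetime

import pytest

from rndvi.thermal import ThermalEntry, ThermalSeries
from rndvi.types import (
    CultivarType,
    NdviObservation,
    ObservationSeries,
    PlotInfo,
    WeatherRecord,
    WeatherSeries,
)

START = datetime.date(2014, 6, 17)


@pytest.fixture
def make_weather():
    """Factory for constant-temperature weather series."""

    def _make(n_days=11, tmin=20.0, tmax=30.0, start=START):
        return WeatherSeries(
            [
                WeatherRecord(start + datetime.timedelta(days=d), tmin, tmax)
                for d in range(n_days)
            ]
        )

    return _make


@pytest.fixture
def make_plot():
    def _make(
        plot_id="P1",
        season=10,
        cultivar="SY63",
        cultivar_type=CultivarType.INDICA,
        n_rate=300.0,
        grain_yield=10.61,
        start=START,
    ):
        return PlotInfo(
            plot_id=plot_id,
            cultivar=cultivar,
            cultivar_type=cultivar_type,
            n_rate=n_rate,
            transplant_date=start,
            harvest_date=start + datetime.timedelta(days=season),
            grain_yield=grain_yield,
        )

    return _make


@pytest.fixture
def make_series():
    """Factory for an observation series from (dat, ndvi) pairs."""

    def _make(plot, points):
        obs = [
            NdviObservation(
                plot_id=plot.plot_id,
                date=plot.transplant_date + datetime.timedelta(days=dat),
                dat=dat,
                ndvi=ndvi,
            )
            for dat, ndvi in points
        ]
        return ObservationSeries(plot=plot, observations=obs)

    return _make


@pytest.fixture
def make_thermal():
    """Factory for a ThermalSeries with prescribed total AGDD.

    AGDD grows linearly to agdd_h over the season, so intermediate
    values can be pinned exactly by choosing agdd_h and season length.
    """

    def _make(plot_id="P1", season=110, agdd_h=1959.0, start=START):
        entries = [
            ThermalEntry(
                date=start + datetime.timedelta(days=d),
                dat=d,
                agdd=agdd_h * (d / season),
                ragdd=d / season,
            )
            for d in range(season + 1)
        ]
        return ThermalSeries(plot_id=plot_id, entries=entries, agdd_h=agdd_h)

    return _make
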