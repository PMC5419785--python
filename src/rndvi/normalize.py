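"""Group NDVI maxima, relative NDVI, and pooled normalized datasets.

NDVI trajectories differ in amplitude across cultivars and nitrogen
treatments, but share a common shape once each group's readings are
divided by that group's seasonal maximum:

    RNDVI_i = NDVI_i / NDVI_max.

NDVI_max is the maximum NDVI of the same treatment or yield level over
the entire growth period — computed from the pooled group data by
default, or supplied externally (e.g. from historical records) via an
override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import numpy as np

from .thermal import ThermalSeries
from .types import ObservationSeries, YieldLevel, assign_yield_level

MIN_GROUP_POINTS = 8

GROUPINGS = ("by_yield_level_and_type", "by_treatment")


@dataclass(frozen=True)
class NdviMaxRecord:
    """The seasonal NDVI maximum of a group and when it occurred."""

    group_key: Hashable
    ndvi_max: float
    dat_at_max: int
    agdd_at_max: float


@dataclass
class NormalizedSeries:
    """Pooled (RAGDD, RNDVI) point cloud for one group."""

    group_key: Hashable
    ragdd: np.ndarray
    rndvi: np.ndarray
    ndvi_max: float | dict[str, float]

    def __post_init__(self) -> None:
        self.ragdd = np.asarray(self.ragdd, dtype=float)
        self.rndvi = np.asarray(self.rndvi, dtype=float)
        if self.ragdd.shape != self.rndvi.shape:
            raise ValueError("ragdd and rndvi must have equal length")

    def __len__(self) -> int:
        return len(self.ragdd)


def find_ndvi_max(
    series_list: Iterable[ObservationSeries],
    thermal: Mapping[str, ThermalSeries],
    group_key: Hashable = None,
) -> NdviMaxRecord:
    """Maximum observed NDVI across a group of plots, with its DAT and AGDD.

    Ties at the maximum are broken by the earliest DAT (then plot id,
    for determinism across pooled plots).
    """
    best = None  # (-ndvi, dat, plot_id) lexicographic minimum
    for series in series_list:
        th = thermal[series.plot.plot_id]
        for obs in series.observations:
            key = (-obs.ndvi, obs.dat, obs.plot_id)
            if best is None or key < best[0]:
                best = (key, obs, th)
    if best is None:
        raise ValueError(f"empty observation group {group_key!r}")
    _, obs, th = best
    return NdviMaxRecord(
        group_key=group_key,
        ndvi_max=obs.ndvi,
        dat_at_max=obs.dat,
        agdd_at_max=th.agdd_at(obs.dat),
    )


def relative_ndvi(ndvi, ndvi_max: float):
    """Relative NDVI: an NDVI reading divided by its group maximum."""
    if ndvi_max <= 0:
        raise ValueError(f"ndvi_max must be positive, got {ndvi_max}")
    out = np.asarray(ndvi, dtype=float) / ndvi_max
    if np.ndim(ndvi) == 0:
        return float(out)
    return out


def _group_key(series: ObservationSeries, grouping: str):
    plot = series.plot
    if grouping == "by_yield_level_and_type":
        if plot.grain_yield is None:
            raise ValueError(
                f"plot {plot.plot_id} lacks grain yield; cannot group by "
                "yield level"
            )
        return (plot.cultivar_type, assign_yield_level(plot.grain_yield))
    if grouping == "by_treatment":
        return (plot.cultivar, plot.n_rate)
    raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")


def build_group_dataset(
    series_list: Iterable[ObservationSeries],
    thermal: Mapping[str, ThermalSeries],
    grouping: str = "by_yield_level_and_type",
    per_cultivar_norm: bool = False,
    ndvi_max_override: Mapping[Hashable, float] | None = None,
) -> list[NormalizedSeries]:
    """Pool plots into groups and normalize each group's point cloud.

    Each group's observations become (RAGDD, RNDVI) pairs normalized by
    the group's NDVI_max (or, with ``per_cultivar_norm``, by each
    cultivar's own maximum before pooling — relevant when a yield-level
    group mixes cultivars of different canopy amplitude). A group with
    fewer than 8 points cannot support a 4-parameter fit and is an
    error.
    """
    groups: dict[Hashable, list[ObservationSeries]] = {}
    for series in series_list:
        groups.setdefault(_group_key(series, grouping), []).append(series)

    out: list[NormalizedSeries] = []
    for key in sorted(groups, key=repr):
        members = groups[key]
        n_points = sum(len(s) for s in members)
        if n_points < MIN_GROUP_POINTS:
            raise ValueError(
                f"group {key!r} has only {n_points} points (< {MIN_GROUP_POINTS}); "
                "unfittable"
            )
        ragdd, rndvi = [], []
        if per_cultivar_norm:
            maxima: dict[str, float] = {}
            for s in members:
                cultivar = s.plot.cultivar
                peak = max(o.ndvi for o in s.observations)
                maxima[cultivar] = max(maxima.get(cultivar, -np.inf), peak)
            if ndvi_max_override and key in ndvi_max_override:
                raise ValueError(
                    "ndvi_max_override and per_cultivar_norm are mutually exclusive"
                )
            for s in members:
                m = maxima[s.plot.cultivar]
                th = thermal[s.plot.plot_id]
                for o in s.observations:
                    ragdd.append(th.ragdd_at(o.dat))
                    rndvi.append(relative_ndvi(o.ndvi, m))
            ndvi_max: float | dict[str, float] = maxima
        else:
            if ndvi_max_override and key in ndvi_max_override:
                m = float(ndvi_max_override[key])
            else:
                m = find_ndvi_max(members, thermal, key).ndvi_max
            for s in members:
                th = thermal[s.plot.plot_id]
                for o in s.observations:
                    ragdd.append(th.ragdd_at(o.dat))
                    rndvi.append(relative_ndvi(o.ndvi, m))
            ndvi_max = m
        cloud = NormalizedSeries(
            group_key=key,
            ragdd=np.array(ragdd),
            rndvi=np.array(rndvi),
            ndvi_max=ndvi_max,
        )
        if np.any(cloud.rndvi < 0):
            warnings.warn(
                f"group {key!r} contains negative RNDVI values (negative NDVI "
                "readings in the input)",
                stacklevel=2,
            )
        out.append(cloud)
    return out


__all__ = [
    "NdviMaxRecord",
    "NormalizedSeries",
    "YieldLevel",
    "assign_yield_level",
    "build_group_dataset",
    "find_ndvi_max",
    "relative_ndvi",
]
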