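import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from rndvi.normalize import (
    build_group_dataset,
    find_ndvi_max,
    relative_ndvi,
)
from rndvi.types import CultivarType, YieldLevel, assign_yield_level


class TestFindNdviMax:
    def test_peak_reading_with_its_dat_and_agdd(
        self, make_plot, make_series, make_thermal
    ):
        """A trajectory peaking at 0.888 on DAT 55 where the accumulated
        thermal time is 979.5 degree-days reports exactly that triple,
        matching the published high-N Indica treatment."""
        plot = make_plot(season=110)
        thermal = make_thermal(season=110, agdd_h=1959.0)
        points = [(10, 0.30), (30, 0.70), (55, 0.888), (80, 0.75), (100, 0.50)]
        series = make_series(plot, points)
        rec = find_ndvi_max([series], {"P1": thermal})
        assert rec.ndvi_max == 0.888
        assert rec.dat_at_max == 55
        assert rec.agdd_at_max == 979.5

    def test_tie_broken_by_earliest_dat(self, make_plot, make_series, make_thermal):
        plot = make_plot(season=110)
        series = make_series(plot, [(10, 0.5), (20, 0.5), (30, 0.5)])
        rec = find_ndvi_max([series], {"P1": make_thermal(season=110)})
        assert rec.ndvi_max == 0.5
        assert rec.dat_at_max == 10

    def test_groups_are_independent(self, make_plot, make_series, make_thermal):
        th = {"A": make_thermal("A", 110), "B": make_thermal("B", 110)}
        sa = make_series(make_plot("A", season=110), [(10, 0.9), (20, 0.8)])
        sb = make_series(make_plot("B", season=110), [(10, 0.4), (20, 0.6)])
        assert find_ndvi_max([sa], th).ndvi_max == 0.9
        assert find_ndvi_max([sb], th).ndvi_max == 0.6

    def test_empty_group_is_error(self, make_thermal):
        with pytest.raises(ValueError, match="empty"):
            find_ndvi_max([], {"P1": make_thermal()})


class TestRelativeNdvi:
    @pytest.mark.parametrize(
        "ndvi,ndvi_max,expected",
        [(0.444, 0.888, 0.5), (0.888, 0.888, 1.0), (0.0, 0.888, 0.0)],
    )
    def test_division(self, ndvi, ndvi_max, expected):
        assert relative_ndvi(ndvi, ndvi_max) == pytest.approx(expected)

    def test_nonpositive_max_rejected(self):
        with pytest.raises(ValueError):
            relative_ndvi(0.5, 0.0)

    def test_normalizing_by_one_is_identity(self):
        vals = np.array([0.1, 0.55, 1.0])
        assert np.array_equal(relative_ndvi(vals, 1.0), vals)


class TestYieldLevels:
    @pytest.mark.parametrize(
        "grain_yield,level",
        [
            (10.61, YieldLevel.HIGH),
            (8.25, YieldLevel.LOW),
            (9.04, YieldLevel.MIDDLE),
            (10.5, YieldLevel.HIGH),
            (6.08, YieldLevel.LOW),
            (10.49, YieldLevel.MIDDLE),
        ],
    )
    def test_published_boundaries(self, grain_yield, level):
        assert assign_yield_level(grain_yield) is level

    def test_negative_yield_rejected(self):
        with pytest.raises(ValueError):
            assign_yield_level(-1.0)


def _two_plot_group(make_plot, make_series, make_thermal, scale=1.0):
    plots = [
        make_plot("A", season=110, grain_yield=10.61),
        make_plot("B", season=110, grain_yield=11.02),
    ]
    thermal = {"A": make_thermal("A", 110), "B": make_thermal("B", 110)}
    pts_a = [(d, scale * v) for d, v in [(10, 0.3), (30, 0.7), (55, 0.886), (80, 0.7)]]
    pts_b = [(d, scale * v) for d, v in [(15, 0.4), (40, 0.8), (55, 0.888), (90, 0.6)]]
    series = [make_series(plots[0], pts_a), make_series(plots[1], pts_b)]
    return series, thermal


class TestBuildGroupDataset:
    def test_pooled_high_yield_cloud_has_unit_max(
        self, make_plot, make_series, make_thermal
    ):
        series, thermal = _two_plot_group(make_plot, make_series, make_thermal)
        (ds,) = build_group_dataset(series, thermal)
        assert ds.group_key == (CultivarType.INDICA, YieldLevel.HIGH)
        assert len(ds) == 8
        assert ds.rndvi.max() == pytest.approx(1.0)
        assert ds.ndvi_max == pytest.approx(0.888)

    def test_by_treatment_partitions_by_n_rate(
        self, make_plot, make_series, make_thermal
    ):
        series, thermal = [], {}
        for i, n_rate in enumerate((0, 75, 150, 225, 300, 375)):
            pid = f"P{i}"
            plot = make_plot(pid, season=110, n_rate=float(n_rate))
            thermal[pid] = make_thermal(pid, 110)
            series.append(
                make_series(plot, [(d, 0.1 + 0.01 * d) for d in range(10, 90, 10)])
            )
        groups = build_group_dataset(series, thermal, grouping="by_treatment")
        assert len(groups) == 6
        assert {k[1] for k in (g.group_key for g in groups)} == {
            0.0, 75.0, 150.0, 225.0, 300.0, 375.0,
        }

    def test_missing_yield_under_yield_grouping_is_error(
        self, make_plot, make_series, make_thermal
    ):
        plot = make_plot(grain_yield=None, season=110)
        series = [make_series(plot, [(d, 0.5) for d in range(10, 90, 10)])]
        with pytest.raises(ValueError, match="lacks grain yield"):
            build_group_dataset(series, {"P1": make_thermal(season=110)})

    def test_small_group_is_unfittable(self, make_plot, make_series, make_thermal):
        plot = make_plot(season=110)
        series = [make_series(plot, [(10, 0.3), (30, 0.7)])]
        with pytest.raises(ValueError, match="unfittable"):
            build_group_dataset(series, {"P1": make_thermal(season=110)})

    def test_override_replaces_computed_maximum(
        self, make_plot, make_series, make_thermal
    ):
        series, thermal = _two_plot_group(make_plot, make_series, make_thermal)
        key = (CultivarType.INDICA, YieldLevel.HIGH)
        (ds,) = build_group_dataset(
            series, thermal, ndvi_max_override={key: 0.9}
        )
        assert ds.ndvi_max == 0.9
        assert ds.rndvi.max() == pytest.approx(0.888 / 0.9)

    @settings(derandomize=True, max_examples=20, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(scale=st.floats(min_value=0.05, max_value=1.1))
    def test_scale_invariance(
        self, make_plot, make_series, make_thermal, scale
    ):
        """Multiplying every NDVI in a group by a positive constant
        leaves the normalized point cloud unchanged."""
        base, thermal = _two_plot_group(make_plot, make_series, make_thermal)
        scaled, _ = _two_plot_group(make_plot, make_series, make_thermal, scale)
        (ds0,) = build_group_dataset(base, thermal)
        (ds1,) = build_group_dataset(scaled, thermal)
        np.testing.assert_allclose(ds1.rndvi, ds0.rndvi, rtol=1e-12)
        np.testing.assert_array_equal(ds1.ragdd, ds0.ragdd)
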