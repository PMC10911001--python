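import numpy as np
import pandas as pd
import pytest

from epeagree.errors import ThresholdUndefinedError
from epeagree.station_exposure import (
    assign_daily_values,
    assign_station_thresholds,
    completeness,
    distance_profile,
    distance_profiles,
    filter_qc,
    local_percentile_threshold,
    select_threshold_stations,
)
from epeagree.types import PrecipSeries, Station, StationNetwork

from conftest import make_network, make_series, square_unit


class TestFilterQc:
    def test_clean_series_unchanged(self):
        s = make_series([1, 2, 3])
        out = filter_qc(s)
        assert np.array_equal(out.values, s.values)

    def test_all_flagged_all_missing(self):
        s = make_series([1, 2, 3], qc=[True, True, True])
        assert np.isnan(filter_qc(s).values).all()

    def test_partial_flags_removed(self):
        vals = np.arange(10, dtype=float)
        qc = np.zeros(10, bool)
        qc[[1, 4, 7]] = True
        out = filter_qc(make_series(vals, qc=qc))
        assert np.isnan(out.values).sum() == 3
        assert np.array_equal(out.values[~np.isnan(out.values)],
                              vals[~qc])


class TestCompleteness:
    def test_full_record(self):
        s = make_series(np.ones(100))
        assert completeness(s, s.dates) == 1.0

    def test_one_missing_of_hundred(self):
        v = np.ones(100)
        v[10] = np.nan
        s = make_series(v)
        assert completeness(s, s.dates) == pytest.approx(0.99)

    def test_flagged_days_count_as_absent(self):
        qc = np.zeros(100, bool)
        qc[[3, 50]] = True
        s = make_series(np.ones(100), qc=qc)
        assert completeness(s, s.dates) == pytest.approx(0.98)

    def test_never_increases_after_filtering(self, rng):
        v = rng.gamma(1, 5, 200)
        v[rng.random(200) < 0.2] = np.nan
        qc = rng.random(200) < 0.1
        s = make_series(v, qc=qc)
        assert completeness(filter_qc(s), s.dates) <= completeness(
            PrecipSeries(s.source_id, s.dates, s.values), s.dates
        )

    def test_empty_period_rejected(self):
        s = make_series([1.0])
        with pytest.raises(ValueError):
            completeness(s, pd.DatetimeIndex([]))


class TestThresholdScreen:
    def test_all_complete_kept(self):
        net = make_network([("A", 0, 0, np.ones(50)), ("B", 1, 1, np.ones(50))])
        sub = select_threshold_stations(net, net.dates)
        assert sub.station_ids == ["A", "B"]

    def test_station_just_below_cut_excluded(self):
        v = np.ones(1000)
        v[:11] = np.nan  # completeness 0.989
        net = make_network([("A", 0, 0, v), ("B", 1, 1, np.ones(1000))])
        sub = select_threshold_stations(net, net.dates)
        assert sub.station_ids == ["B"]

    def test_exactly_at_cut_included(self):
        v = np.ones(1000)
        v[:10] = np.nan  # completeness 0.990
        net = make_network([("A", 0, 0, v)])
        assert select_threshold_stations(net, net.dates).station_ids == ["A"]

    def test_empty_result_warns(self):
        v = np.full(100, np.nan)
        v[0] = 1.0
        net = make_network([("A", 0, 0, v)])
        with pytest.warns(UserWarning):
            sub = select_threshold_stations(net, net.dates)
        assert len(sub) == 0


class TestLocalThreshold:
    def test_linear_interpolation_quantile(self):
        s = make_series(np.arange(1.0, 101.0))
        assert local_percentile_threshold(s) == pytest.approx(99.01)

    def test_constant_wet_days(self):
        s = make_series([5.0, 5.0, 0.0, 5.0])
        assert local_percentile_threshold(s) == 5.0

    def test_all_dry_raises(self):
        s = make_series(np.zeros(30))
        with pytest.raises(ThresholdUndefinedError):
            local_percentile_threshold(s)

    def test_wet_min_excludes_trace(self):
        s = make_series([0.1, 0.2, 10.0, 20.0])
        thr_default = local_percentile_threshold(s, q=0.5)
        thr_trace = local_percentile_threshold(s, q=0.5, wet_min_mm=0.5)
        assert thr_trace > thr_default

    def test_own_series_exceedance_bound(self, rng):
        # count of days strictly above the 99th wet-day percentile is at
        # most ceil(1% of wet days)
        v = rng.gamma(0.8, 8, 2000) * (rng.random(2000) < 0.4)
        s = make_series(v)
        thr = local_percentile_threshold(s)
        wet = v[v > 0]
        assert (wet > thr).sum() <= np.ceil(0.01 * wet.size)


class TestAssignThresholds:
    def test_single_station_shared(self):
        net = make_network([("A", 5, 5, np.ones(400) * 3)])
        units = [square_unit("u1", 0, 0), square_unit("u2", 3, 3)]
        out = assign_station_thresholds(units, net)
        assert out["u1"] == out["u2"] == (3.0, "A")

    def test_equidistant_tie_prefers_lower_id(self):
        net = make_network(
            [("B", 2.0, 0.0, np.ones(10)), ("A", 0.0, 2.0, np.ones(10) * 2)]
        )
        unit = square_unit("u", 0.5, 0.5, side=1.0)  # centroid (1,1) equidistant
        out = assign_station_thresholds([unit], net)
        assert out["u"][1] == "A"

    def test_matches_brute_force(self, rng):
        n_st, n_units = 20, 30
        specs = [
            (f"S{i:02d}", rng.uniform(0, 50), rng.uniform(0, 50),
             rng.gamma(1, 5, 500))
            for i in range(n_st)
        ]
        net = make_network(specs)
        units = [
            square_unit(f"u{i:02d}", rng.uniform(0, 49), rng.uniform(0, 49))
            for i in range(n_units)
        ]
        out = assign_station_thresholds(units, net)
        thr = {
            s.station_id: local_percentile_threshold(s.series)
            for s in net.stations
        }
        for u in units:
            cx, cy = u.centroid
            best = min(
                net.stations,
                key=lambda s: (np.hypot(s.x - cx, s.y - cy), s.station_id),
            )
            assert out[u.unit_id] == (thr[best.station_id], best.station_id)


class TestAssignDailyValues:
    def test_single_station_passthrough(self):
        vals = np.array([1.0, np.nan, 3.0])
        net = make_network([("A", 0, 0, vals)])
        units = [square_unit("u", 10, 10)]
        out = assign_daily_values(units, net)
        assert np.array_equal(out["u"].values, vals, equal_nan=True)

    def test_falls_back_to_second_nearest_when_offline(self):
        near = np.array([1.0, np.nan, 1.0])
        far = np.array([9.0, 9.0, 9.0])
        net = make_network([("near", 1, 0, near), ("far", 5, 0, far)])
        units = [square_unit("u", -0.5, -0.5)]
        out = assign_daily_values(units, net)["u"].values
        assert np.array_equal(out, [1.0, 9.0, 1.0])

    def test_flagged_station_day_skipped(self):
        s_near = make_series([1.0, 1.0], "near", qc=[False, True])
        s_far = make_series([9.0, 9.0], "far")
        net = StationNetwork(
            [Station("near", 1, 0, s_near), Station("far", 5, 0, s_far)]
        )
        out = assign_daily_values([square_unit("u", -0.5, -0.5)], net)["u"]
        assert np.array_equal(out.values, [1.0, 9.0])

    def test_no_station_reporting_gives_missing(self):
        net = make_network([("A", 0, 0, np.array([np.nan, 2.0]))])
        out = assign_daily_values([square_unit("u", 5, 5)], net)["u"]
        assert np.isnan(out.values[0]) and out.values[1] == 2.0

    def test_matches_daily_brute_force_oracle(self, rng):
        n_st, n_units, n_days = 15, 20, 120
        vals = rng.gamma(1, 5, (n_days, n_st))
        vals[rng.random((n_days, n_st)) < 0.3] = np.nan
        specs = [
            (f"S{i:02d}", rng.uniform(0, 30), rng.uniform(0, 30), vals[:, i])
            for i in range(n_st)
        ]
        net = make_network(specs)
        units = [
            square_unit(f"u{i}", rng.uniform(0, 29), rng.uniform(0, 29))
            for i in range(n_units)
        ]
        got = assign_daily_values(units, net)
        for u in units:
            cx, cy = u.centroid
            dists = [
                (np.hypot(s.x - cx, s.y - cy), s.station_id, k)
                for k, s in enumerate(net.stations)
            ]
            for d in range(n_days):
                cands = [
                    (dist, sid) for dist, sid, k in dists
                    if not np.isnan(vals[d, k])
                ]
                if not cands:
                    assert np.isnan(got[u.unit_id].values[d])
                else:
                    dist, sid = min(cands)
                    k = net.station_ids.index(sid)
                    assert got[u.unit_id].values[d] == vals[d, k]


class TestDistanceProfile:
    def test_static_network_mean_is_static_distance(self):
        net = make_network([("A", 3.0, 0.0, np.ones(10))])
        unit = square_unit("u", -0.5, -0.5)  # centroid origin
        p = distance_profile(unit, net)
        assert p.mean_daily_distance_km == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "d,stratum",
        [(6.999, "0–7 km"), (7.0, "7–30 km"), (30.0, "7–30 km"), (30.001, ">30 km")],
    )
    def test_stratum_boundaries(self, d, stratum):
        net = make_network([("A", d, 0.0, np.ones(5))])
        p = distance_profile(square_unit("u", -0.5, -0.5), net)
        assert p.stratum == stratum

    def test_outage_shifts_daily_nearest(self):
        near = np.array([1.0, np.nan])
        far = np.array([1.0, 1.0])
        net = make_network([("near", 4.0, 0.0, near), ("far", 10.0, 0.0, far)])
        p = distance_profile(square_unit("u", -0.5, -0.5), net)
        assert p.mean_daily_distance_km == pytest.approx((4.0 + 10.0) / 2)

    def test_adding_station_never_increases_distance(self, rng):
        vals = rng.gamma(1, 5, (50, 5))
        specs = [
            (f"S{i}", rng.uniform(0, 20), rng.uniform(0, 20), vals[:, i])
            for i in range(5)
        ]
        units = [
            square_unit(f"u{i}", rng.uniform(0, 19), rng.uniform(0, 19))
            for i in range(10)
        ]
        before = distance_profiles(units, make_network(specs))
        specs.append(("S9", 10.0, 10.0, np.ones(50)))
        after = distance_profiles(units, make_network(specs))
        for uid in before:
            assert (
                after[uid].mean_daily_distance_km
                <= before[uid].mean_daily_distance_km + 1e-12
            )
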